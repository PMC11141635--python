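"""Spike-in calibrated ChIP-seq region quantification.

Four stages around a region × sample signal table (AUC = area under the
per-base normalized coverage curve over the region, plus raw read counts):

1. :func:`spikein_scale_factors` — exogenous Drosophila (dm6) chromatin is
   spiked into each sample, so the per-sample uniquely-mapped dm6 totals
   calibrate global signal differences; the factor for sample s is
   mean(dm6 counts over samples) / dm6 count of s, and multiplying each
   sample's human signal by its factor equalizes spike-in totals exactly.
2. :func:`curate_peaks` — drop called regions with low coverage
   (log2(AUC+1) < 13 by default) and regions overlapping a blacklist by
   >= 1 bp.
3. :func:`merge_condition_peaks` — union per-condition peak sets into one
   aggregated, sorted set (touching intervals merge).
4. :func:`differential_regions` — classify each region between two
   conditions as increase / decrease / not_significant: the effect gate is
   |delta| >= 1.5 on the difference of condition means of log2(AUC+1), and
   the significance gate p <= 0.10 comes from a negative-binomial
   likelihood-ratio test on the read counts with a single common
   dispersion estimated across regions by method of moments (an exact
   group-relabeling permutation test is available for small designs).

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import optimize, special, stats

from .io import validate_regions

__all__ = [
    "DifferentialRegionCall",
    "spikein_scale_factors",
    "curate_peaks",
    "merge_condition_peaks",
    "differential_regions",
    "AUC_MIN_LOG2",
    "DELTA_CUTOFF",
    "P_CUTOFF",
]

AUC_MIN_LOG2 = 13.0   # curation: keep regions with log2(AUC+1) >= 13
DELTA_CUTOFF = 1.5    # |delta log2(AUC+1)| gate for differential calls
P_CUTOFF = 0.10       # count-test significance gate


@dataclass(frozen=True)
class DifferentialRegionCall:
    """Per-region differential verdict between two conditions."""

    region: str
    delta: float     # mean log2(AUC+1), condition minus reference
    p: float
    call: str        # increase | decrease | not_significant


def spikein_scale_factors(spike_counts: pd.Series) -> pd.Series:
    """Per-sample scale factors from uniquely mapped spike-in (dm6) counts.

    factor_s = mean over samples of the dm6 count, divided by sample s's
    dm6 count. Multiplying each sample's human signal by its factor makes
    every sample's spike-in total equal to the pre-scaling cross-sample
    mean. Counts must be positive; a zero count is an error naming the
    sample.
    """
    counts = spike_counts.astype(float)
    if counts.empty:
        raise ValueError("no spike-in samples")
    bad = counts.index[(counts <= 0) | counts.isna()]
    if len(bad):
        raise ValueError(f"non-positive spike-in count for sample(s) {list(bad)}")
    return counts.mean() / counts


def _blacklist_trees(blacklist: pd.DataFrame) -> dict[str, IntervalTree]:
    validate_regions(blacklist)
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in blacklist.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    return trees


def curate_peaks(
    regions: pd.DataFrame,
    blacklist: pd.DataFrame | None = None,
    auc_min_log2: float = AUC_MIN_LOG2,
    auc_column: str = "auc",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Curate called peaks by coverage and blacklist overlap.

    Drops regions whose ``log2(AUC+1)`` in ``auc_column`` is below
    ``auc_min_log2`` (boundary kept: log2(AUC+1) == threshold is retained)
    and regions overlapping any blacklist interval by at least 1 bp.
    Returns the retained table plus removal counts per criterion
    (``low_auc``, ``blacklist``, ``retained``); low-AUC removal is counted
    first, so the two counts plus the output size equal the input size.
    """
    validate_regions(regions)
    if auc_column not in regions.columns:
        raise ValueError(f"regions table lacks AUC column {auc_column!r}")
    auc = regions[auc_column].astype(float)
    if (auc < 0).any():
        raise ValueError("AUC values must be >= 0")
    low = np.log2(auc + 1.0) < auc_min_log2

    in_blacklist = np.zeros(len(regions), dtype=bool)
    if blacklist is not None and len(blacklist):
        trees = _blacklist_trees(blacklist)
        for i, (_, r) in enumerate(regions.iterrows()):
            tree = trees.get(str(r["chrom"]))
            if tree is not None and tree.overlap(int(r["start"]), int(r["end"])):
                in_blacklist[i] = True

    removed_low = int(low.sum())
    removed_bl = int((~low.to_numpy() & in_blacklist).sum())
    keep = ~low.to_numpy() & ~in_blacklist
    out = regions.loc[keep].copy()
    counts = {"low_auc": removed_low, "blacklist": removed_bl, "retained": int(keep.sum())}
    return out, counts


def merge_condition_peaks(*region_tables: pd.DataFrame) -> pd.DataFrame:
    """Union per-condition peak sets into one aggregated sorted region table.

    Intervals that overlap or touch end-to-start are merged. Idempotent:
    merging a merged table with itself returns the same table.
    """
    if not region_tables:
        raise ValueError("no region tables given")
    frames = []
    for t in region_tables:
        validate_regions(t)
        frames.append(t[["chrom", "start", "end"]])
    allr = pd.concat(frames, ignore_index=True)
    allr = allr.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    merged: list[tuple[str, int, int]] = []
    for chrom, grp in allr.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"].astype(int), grp["end"].astype(int)):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or 0-gap adjacency
                cur_e = max(cur_e, e)
            else:
                merged.append((str(chrom), cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((str(chrom), cur_s, cur_e))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    out["name"] = [f"{c}:{s}-{e}" for c, s, e in merged]
    return out


# --- negative-binomial likelihood-ratio machinery -------------------------

def _nb_loglik(counts: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood; phi -> 0 degenerates to Poisson."""
    counts = np.asarray(counts, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if phi <= 1e-12:
        return float(np.sum(counts * np.log(mu) - mu - special.gammaln(counts + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(counts + r) - special.gammaln(r) - special.gammaln(counts + 1.0)
            + r * np.log(r / (r + mu)) + counts * np.log(mu / (r + mu))
        )
    )


def _nb_mu_mle(counts: np.ndarray, sizes: np.ndarray, phi: float) -> float:
    """MLE of the base mean with per-sample size offsets (mu_s = mu*size_s)."""
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    start = max(counts.sum() / sizes.sum(), 1e-12)
    if phi <= 1e-12 or np.allclose(sizes, sizes[0]):
        return start  # Poisson MLE, and exact for NB with equal sizes

    def score(mu: float) -> float:
        m = mu * sizes
        return float(np.sum((counts - m) / (mu * (1.0 + phi * m))))

    lo, hi = start * 1e-3, start * 1e3
    try:
        return float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12))
    except ValueError:
        return start


def estimate_common_dispersion(counts: pd.DataFrame, groups: Mapping[str, Sequence[str]]) -> float:
    """Method-of-moments NB dispersion shared across regions.

    Within each condition, var = mu + phi*mu^2 gives a per-region phi
    estimate (v - m)/m^2 pooled over conditions; the common phi is the
    median of the finite estimates, floored at 0.
    """
    phis = []
    for _, samples in groups.items():
        sub = counts[list(samples)].to_numpy(dtype=float)
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        phis.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not phis:
        return 0.0
    allphi = np.concatenate(phis)
    if allphi.size == 0:
        return 0.0
    return float(max(np.median(allphi), 0.0))


def _lrt_pvalue(g1: np.ndarray, g2: np.ndarray, phi: float,
                s1: np.ndarray, s2: np.ndarray) -> float:
    mu0 = _nb_mu_mle(np.concatenate([g1, g2]), np.concatenate([s1, s2]), phi)
    mu1 = _nb_mu_mle(g1, s1, phi)
    mu2 = _nb_mu_mle(g2, s2, phi)
    ll0 = _nb_loglik(g1, mu0 * s1, phi) + _nb_loglik(g2, mu0 * s2, phi)
    ll1 = _nb_loglik(g1, mu1 * s1, phi) + _nb_loglik(g2, mu2 * s2, phi)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return float(stats.chi2.sf(lr, 1))


def _permutation_pvalue(y1: np.ndarray, y2: np.ndarray) -> float:
    """Exact permutation p on |difference of group means| over relabelings."""
    pooled = np.concatenate([y1, y2])
    n1 = y1.size
    obs = abs(y1.mean() - y2.mean())
    total = 0
    extreme = 0
    idx = range(pooled.size)
    for comb in combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        d = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if d >= obs - 1e-12:
            extreme += 1
    return extreme / total


def differential_regions(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    aucs: pd.DataFrame,
    delta_cutoff: float = DELTA_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    condition_order: tuple[str, str] | None = None,
    scale_factors: pd.Series | None = None,
    method: str = "nb_lrt",
) -> list[DifferentialRegionCall]:
    """Classify regions as increase / decrease / not_significant.

    Parameters
    ----------
    counts
        Region × sample read counts (raw integers; supply spike-in/library
        ``scale_factors`` if the samples are not already comparable).
    groups
        Mapping of exactly two condition names to their sample lists.
    aucs
        Region × sample AUC signal (spike-in scaled upstream).
    delta_cutoff, p_cutoff
        The |delta| >= 1.5 and p <= 0.10 gates; *both* must pass for a
        non-null call.
    condition_order
        (condition, reference): delta = mean log2(AUC+1) of condition
        minus reference. Defaults to the mapping's iteration order.
    scale_factors
        Optional per-sample factors (e.g. from
        :func:`spikein_scale_factors`); modeled as NB mean offsets
        mu_s = mu / factor_s so scaled signals are comparable.
    method
        ``"nb_lrt"`` (default) or ``"permutation"`` (exact relabeling test
        on mean log2 counts; small designs only).
    """
    if len(groups) != 2:
        raise ValueError("exactly two conditions required")
    names = list(condition_order) if condition_order else list(groups)
    if set(names) != set(groups):
        raise ValueError("condition_order must name the two groups")
    cond, ref = names
    for nm in names:
        if len(groups[nm]) == 0:
            raise ValueError(f"condition {nm!r} has zero replicates")
    if method not in ("nb_lrt", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    cols1 = list(groups[cond])
    cols2 = list(groups[ref])
    y1 = counts[cols1].to_numpy(dtype=float)
    y2 = counts[cols2].to_numpy(dtype=float)
    # scale factors multiply signal; as offsets, the modeled mean per sample
    # is mu / factor (a sample with few spike-in reads was sequenced deeper)
    if scale_factors is not None:
        s1 = 1.0 / scale_factors[cols1].to_numpy(dtype=float)
        s2 = 1.0 / scale_factors[cols2].to_numpy(dtype=float)
    else:
        s1 = np.ones(len(cols1))
        s2 = np.ones(len(cols2))

    a1 = np.log2(aucs[cols1].to_numpy(dtype=float) + 1.0).mean(axis=1)
    a2 = np.log2(aucs[cols2].to_numpy(dtype=float) + 1.0).mean(axis=1)
    delta = a1 - a2

    phi = estimate_common_dispersion(counts, groups) if method == "nb_lrt" else 0.0

    calls: list[DifferentialRegionCall] = []
    for i, region in enumerate(counts.index):
        r1, r2 = y1[i], y2[i]
        if r1.sum() == 0 and r2.sum() == 0:
            p = 1.0
        elif method == "nb_lrt":
            p = _lrt_pvalue(r1, r2, phi, s1, s2)
        else:
            p = _permutation_pvalue(np.log2(r1 / s1 + 1.0), np.log2(r2 / s2 + 1.0))
        d = float(delta[i])
        if d >= delta_cutoff and p <= p_cutoff:
            call = "increase"
        elif d <= -delta_cutoff and p <= p_cutoff:
            call = "decrease"
        else:
            call = "not_significant"
        calls.append(DifferentialRegionCall(str(region), d, p, call))
    return calls
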