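"""Gene-set enrichment statistics for complex-level dependency analysis.

Three related statistics operate on gene sets (e.g. CORUM protein
complexes) against the screen results:

* :func:`gsea_preranked` — weighted Kolmogorov-Smirnov enrichment of a set
  in a signed ranked gene list (differential dependency, expression fold
  change, ...), with a gene-label permutation null, normalized enrichment
  scores (NES), nominal p-values and a GSEA-style FDR. This is the Fig-1A
  style volcano input: one row per complex.
* :func:`ssgsea_score` — single-sample enrichment: for every (gene set,
  sample) pair, the integral of the difference between the weighted in-set
  ECDF and the uniform out-set ECDF along that sample's gene ranking. On a
  dependency matrix this yields per-line complex "metagene" scores, which
  :func:`zscore_across_samples` standardizes into dependency z-scores.
* :func:`overlap_test` / :func:`fisher_exact_2x2` — hypergeometric
  upper-tail and two-tailed Fisher tests for set overlaps.

The running-sum enrichment score for a set S in a list of N genes with
scores s_1 >= ... >= s_N and weight exponent p is the signed extremum of

    sum_{j <= i, j in S} |s_j|^p / NR  -  sum_{j <= i, j not in S} 1/(N-|S|)

with NR the total in-set weight; p = 1 (the weighted scheme) is the
default, p = 0 gives the classic unweighted KS statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffdep import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "SsgseaParams",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "ssgsea_score",
    "zscore_across_samples",
    "overlap_test",
    "fisher_exact_2x2",
    "significant_sets",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending signed score; ties broken by gene id."""

    genes: tuple[str, ...]
    scores: np.ndarray
    n_excluded: int = 0  # NaN-scored genes dropped during construction

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate gene identifiers")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """One gene set's enrichment against a ranked list."""

    name: str
    size: int  # members present in the ranked list
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: tuple[str, ...] = ()
    skipped: str | None = None  # reason, for sets that could not be scored


@dataclass(frozen=True)
class SsgseaParams:
    """Single-sample enrichment parameters.

    alpha is the rank-weighting exponent (0.25, the method's published
    default); ``normalize`` divides all scores by the global max - min range.
    """

    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


def rank_genes(scores: pd.Series | Mapping[str, float]) -> RankedList:
    """Build a ranked list from per-gene signed scores.

    Sorting is by descending score with deterministic lexicographic
    tie-breaking on the gene identifier; NaN scores are excluded and
    counted in ``n_excluded``.
    """
    s = pd.Series(scores, dtype=float)
    if s.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in scores")
    n_excluded = int(s.isna().sum())
    s = s.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return RankedList(
        genes=tuple(str(g) for g in order),
        scores=s.loc[order].to_numpy(dtype=float),
        n_excluded=n_excluded,
    )


def _running_sum(weights: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Cumulative P_hit - P_miss along the list for one set (hit mask)."""
    n = weights.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a proper non-empty subset of the list")
    nr = weights[hit].sum()
    if nr == 0:
        raise ValueError("all in-set weights are zero")
    inc = np.where(hit, weights / nr, -1.0 / (n - n_hit))
    return np.cumsum(inc)


def enrichment_score(
    ranked: RankedList, members: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score of a gene set in a ranked list.

    Returns the signed extremum of the running sum together with the full
    running-sum curve. The set is first restricted to members present in
    the list.
    """
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in ranked.genes), dtype=bool, count=len(ranked))
    weights = np.abs(ranked.scores) ** weight
    running = _running_sum(weights, hit)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _leading_edge(ranked: RankedList, hit: np.ndarray, running: np.ndarray, es: float) -> tuple[str, ...]:
    if es >= 0:
        peak = int(np.argmax(np.abs(running)))
        idx = np.nonzero(hit[: peak + 1])[0]
    else:
        trough = int(np.argmax(np.abs(running)))
        idx = np.nonzero(hit[trough:])[0] + trough
    return tuple(ranked.genes[i] for i in idx)


def _permutation_es(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene-label sets (vectorized)."""
    n = weights.size
    r = rng.random((n_perm, n))
    idx = np.argpartition(r, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    w = np.broadcast_to(weights, (n_perm, n))
    nr = np.where(hits, w, 0.0).sum(axis=1, keepdims=True)
    # random sets whose members all carry zero weight cannot be scored; the
    # caller guarantees nr > 0 for the observed set, and with any nonzero
    # weights present a zero-weight draw has probability ~0 — guard anyway
    nr = np.where(nr == 0, np.nan, nr)
    inc = np.where(hits, w / nr, -1.0 / (n - set_size))
    running = np.cumsum(inc, axis=1)
    pos = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pos]


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
    min_size: int = 1,
    max_size: int = 5000,
    fdr_method: str = "auto",
) -> list[EnrichmentResult]:
    """Preranked GSEA of every gene set against a ranked list.

    The null is n_perm random gene-label sets of identical size (seeded);
    NES divides ES by the mean absolute same-sign permutation ES, the
    nominal p is the one-sided frequency among same-sign permutation ESs,
    and the FDR follows the GSEA-software global same-sign NES-ratio scheme
    (``fdr_method="gsea"``) or Benjamini-Hochberg on the nominal p
    (``"bh"``); ``"auto"`` uses BH below 500 permutations, where the pooled
    NES tail is too coarse.

    Sets are restricted to members present in the list; sets whose
    restricted size falls outside [min_size, max_size], or that cover the
    whole list, are emitted with ``skipped`` set and NaN statistics.
    """
    if fdr_method not in ("gsea", "bh", "auto"):
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    if fdr_method == "auto":
        fdr_method = "gsea" if n_perm >= 500 else "bh"
    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.scores) ** weight
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}

    results: list[EnrichmentResult] = []
    perm_nes_pool: list[np.ndarray] = []
    scored: list[tuple[int, np.ndarray, bool]] = []  # (result idx, perm ES, has null)

    for gs in sets:
        present = [g for g in gs.genes if g in gene_pos]
        size = len(present)
        if size < min_size or size > max_size:
            results.append(
                EnrichmentResult(gs.name, size, np.nan, np.nan, np.nan, np.nan,
                                 skipped=f"size {size} outside [{min_size}, {max_size}]")
            )
            continue
        if size == n:
            raise ValueError(f"gene set {gs.name!r} equals the ranked universe")
        hit = np.zeros(n, dtype=bool)
        hit[[gene_pos[g] for g in present]] = True
        nr = weights[hit].sum()
        if nr == 0:
            results.append(
                EnrichmentResult(gs.name, size, np.nan, np.nan, np.nan, np.nan,
                                 skipped="all in-set weights zero")
            )
            continue
        running = _running_sum(weights, hit)
        es = float(running[np.argmax(np.abs(running))])
        perm_es = _permutation_es(weights, size, n_perm, rng)
        perm_es = perm_es[np.isfinite(perm_es)]

        same_sign = perm_es[perm_es >= 0] if es >= 0 else perm_es[perm_es < 0]
        if same_sign.size == 0:
            results.append(
                EnrichmentResult(gs.name, size, es, np.nan, np.nan, np.nan,
                                 _leading_edge(ranked, hit, running, es),
                                 skipped="no same-sign permutation ES"))
            continue
        mean_abs = np.abs(same_sign).mean()
        nes = es / mean_abs
        p = float(np.mean(np.abs(same_sign) >= abs(es)))
        res = EnrichmentResult(gs.name, size, es, nes, p, np.nan,
                               _leading_edge(ranked, hit, running, es))
        scored.append((len(results), perm_es, True))
        results.append(res)

    if fdr_method == "bh":
        idx = [i for i, _, _ in scored]
        qs = bh_adjust([results[i].p for i in idx])
        for i, q in zip(idx, qs):
            results[i].fdr = float(q)
        return results

    # GSEA-style global FDR: normalize each set's permutation ESs into NES
    # using that set's same-sign means, pool them, and compare tail areas.
    for i, perm_es, _ in scored:
        pos = perm_es[perm_es >= 0]
        neg = perm_es[perm_es < 0]
        norm = np.empty_like(perm_es)
        norm[perm_es >= 0] = perm_es[perm_es >= 0] / (pos.mean() if pos.size else np.nan)
        norm[perm_es < 0] = perm_es[perm_es < 0] / np.abs(neg.mean()) if neg.size else np.nan
        perm_nes_pool.append(norm)
    pool = np.concatenate(perm_nes_pool) if perm_nes_pool else np.array([])
    obs = np.array([results[i].nes for i, _, _ in scored])
    for (i, _, _), nes in zip(scored, obs):
        if nes >= 0:
            num_denom = np.mean(pool >= 0) or np.nan
            num = np.mean(pool >= nes) / num_denom
            den_denom = np.mean(obs >= 0) or np.nan
            den = np.mean(obs >= nes) / den_denom
        else:
            num_denom = np.mean(pool < 0) or np.nan
            num = np.mean(pool <= nes) / num_denom
            den_denom = np.mean(obs < 0) or np.nan
            den = np.mean(obs <= nes) / den_denom
        fdr = num / den if den > 0 else np.nan
        results[i].fdr = float(min(fdr, 1.0)) if np.isfinite(fdr) else np.nan
    return results


def significant_sets(
    results: Sequence[EnrichmentResult],
    min_abs_nes: float = 1.3,
    max_p: float = 0.05,
    max_fdr: float = 0.25,
) -> list[EnrichmentResult]:
    """Filter enrichment results at the |NES| >= 1.3, p <= 0.05, FDR <= 0.25 rule.

    All three thresholds are parameters; alternative cutoffs (e.g. a plain
    -log10 p gate) can be expressed by relaxing the others.
    """
    out = []
    for r in results:
        if r.skipped or not np.isfinite(r.nes):
            continue
        if abs(r.nes) >= min_abs_nes and r.p <= max_p and r.fdr <= max_fdr:
            out.append(r)
    return out


def ssgsea_score(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
) -> pd.DataFrame:
    """Single-sample enrichment scores for every (gene set, sample) pair.

    Per sample, genes with non-missing values are ranked descending (ties:
    average ranks for the weights, lexicographic gene order for list
    positions) and the score is the sum over all list positions of the
    difference between the weighted in-set step ECDF (weights rank^alpha)
    and the uniform out-set step ECDF — an integral, not an extremum. With
    ``params.normalize`` the whole set × sample score matrix is divided by
    its max - min range.

    Sets with no members in a sample's genes yield NaN for that sample.
    """
    scores = pd.DataFrame(index=sets.names(), columns=matrix.columns, dtype=float)
    member_masks = {gs.name: set(gs.genes) for gs in sets}
    for sample in matrix.columns:
        col = matrix[sample].dropna()
        n = len(col)
        if n == 0:
            continue
        order = sorted(col.index, key=lambda g: (-col[g], str(g)))
        values = col.loc[order].to_numpy(dtype=float)
        # weight of the gene at list position i: its average rank counted
        # from the bottom (ties averaged), so the top gene carries ~N^alpha
        bottom_ranks = stats.rankdata(values, method="average")
        w = bottom_ranks ** params.alpha
        genes = [str(g) for g in order]
        for name, members in member_masks.items():
            hit = np.fromiter((g in members for g in genes), dtype=bool, count=n)
            n_hit = int(hit.sum())
            if n_hit == 0:
                scores.loc[name, sample] = np.nan
                continue
            if n_hit == n:
                scores.loc[name, sample] = np.nan
                continue
            wr = w[hit].sum()
            cum_in = np.cumsum(np.where(hit, w, 0.0)) / wr
            cum_out = np.cumsum(np.where(hit, 0.0, 1.0)) / (n - n_hit)
            scores.loc[name, sample] = float(np.sum(cum_in - cum_out))
    if params.normalize:
        vals = scores.to_numpy(dtype=float)
        if np.isfinite(vals).any():
            rng_span = np.nanmax(vals) - np.nanmin(vals)
            if rng_span > 0:
                scores = scores / rng_span
    return scores


def zscore_across_samples(scores: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize a set × sample score matrix across samples (per set).

    Uses the sample standard deviation (ddof=1) by convention. Sets whose
    scores are constant get all-zero z-scores with a warning; fewer than two
    non-missing samples for a set is an error.
    """
    z = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for name, row in scores.iterrows():
        vals = row.astype(float)
        ok = vals.notna()
        if ok.sum() < 2:
            raise ValueError(f"set {name!r}: need >=2 samples with non-missing scores")
        sd = vals[ok].std(ddof=ddof)
        if sd == 0:
            warnings.warn(f"set {name!r}: constant scores, z set to 0", RuntimeWarning,
                          stacklevel=2)
            z.loc[name] = np.where(ok, 0.0, np.nan)
        else:
            z.loc[name] = (vals - vals[ok].mean()) / sd
    return z


def overlap_test(
    hits: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Hypergeometric upper-tail overlap test P(X >= k).

    ``hits`` and ``gene_set`` must be subsets of ``universe``; returns the
    overlap count and the probability of an overlap at least that large
    when ``len(hits)`` genes are drawn without replacement.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    gene_set = set(gene_set)
    if not hits <= universe or not gene_set <= universe:
        raise ValueError("hits and gene_set must be subsets of the universe")
    k = len(hits & gene_set)
    m, n_set, n_hits = len(universe), len(gene_set), len(hits)
    p = float(stats.hypergeom.sf(k - 1, m, n_set, n_hits))
    return k, min(p, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2×2 table [[a, b], [c, d]].

    Two-tailed by summing all tables (fixed margins) whose point
    probability does not exceed the observed table's.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("table entries must be non-negative integers")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
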