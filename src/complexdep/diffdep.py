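"""Two-class differential dependency with empirical-Bayes variance moderation.

Given a genes × cell-lines dependency matrix (Chronos-like gene-effect
scores) and a split of the lines into an in-group (e.g. MYCN-amplified
neuroblastoma) and an out-group (all other screened lines), each gene is
tested for a difference in mean dependency with a moderated t-statistic:

    s_g^2     pooled residual variance, d_g = n_in + n_out - 2 df
    s~_g^2  = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g     = (mean_in - mean_out) / (s~_g * sqrt(1/n_in + 1/n_out))

with t_g referred to a t distribution on d0 + d_g degrees of freedom. The
prior (d0, s0^2) is estimated across genes by the standard method of
moments on log s_g^2 (digamma/trigamma inversion); d0 = 0 recovers the
ordinary pooled two-sample t exactly, and d0 = inf (all variances shrunk to
s0^2) is supported as a limit. P-values are two-sided and adjusted across
tested genes by Benjamini-Hochberg.

Missing dependency values are removed per gene per group (pairwise
deletion); genes with fewer than two non-missing values in either group are
reported with missing statistics and a reason, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ModerationParams", "two_class", "bh_adjust", "fit_moderation"]


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: d0 prior degrees of freedom, s0_sq prior variance.

    ``d0 = 0`` disables shrinkage (ordinary pooled t); ``d0 = inf`` shrinks
    every gene's variance fully to ``s0_sq``.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not np.isinf(self.d0) and self.s0_sq < 0:
            raise ValueError(f"s0_sq must be >= 0, got {self.s0_sq}")


def bh_adjust(p_values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with enforced monotonicity.

    NaN entries are propagated (excluded from the adjustment, returned NaN).
    Values outside [0, 1] raise a validation error.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the standard monotone-convergent update on 1/y. Returns inf when x
    is non-positive (no finite solution: trigamma > 0 everywhere).
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x  # good starting value for all x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_moderation(s_sq: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Estimate (d0, s0^2) from per-gene sample variances by moments of log s^2.

    Under the scaled-inverse-chi-square prior, e_g = log s_g^2
    - digamma(d_g/2) + log(d_g/2) has mean log s0^2 + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2) beyond trigamma(d_g/2);
    d0 follows by trigamma inversion. When the excess is non-positive the
    observed variances are less dispersed than sampling alone predicts and
    the infinite-d0 limit is returned with a warning.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    keep = np.isfinite(s_sq) & (s_sq > 0) & (df > 0)
    s_sq, df = s_sq[keep], df[keep]
    if s_sq.size < 2:
        raise ValueError("need >=2 genes with positive variance to fit the prior")
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    n = e.size
    excess = float(np.mean((e - e_bar) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)))
    half_d0 = _trigamma_inverse(excess)
    if np.isinf(half_d0):
        warnings.warn(
            "log-variance dispersion not above sampling noise; using the d0=inf limit",
            RuntimeWarning,
            stacklevel=2,
        )
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_bar + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def _group_stats(values: np.ndarray) -> tuple[int, float, float]:
    """n, mean, sum of squared deviations over non-missing entries."""
    v = values[~np.isnan(values)]
    n = v.size
    if n == 0:
        return 0, np.nan, np.nan
    m = float(v.mean())
    return n, m, float(((v - m) ** 2).sum())


def two_class(
    dep: pd.DataFrame,
    in_lines: Sequence[str],
    out_lines: Sequence[str],
    moderation: ModerationParams | None = None,
) -> pd.DataFrame:
    """Differential dependency of every gene between two groups of cell lines.

    Parameters
    ----------
    dep
        Genes × lines dependency matrix (NaN = missing).
    in_lines, out_lines
        Disjoint cell-line groups; each tested gene needs >=2 non-missing
        values per group, others are emitted with NaN statistics and a
        ``reason``.
    moderation
        Fixed empirical-Bayes prior; default None estimates (d0, s0^2)
        across genes by :func:`fit_moderation`.

    Returns
    -------
    DataFrame indexed by gene with columns ``n_in``, ``n_out``, ``mean_in``,
    ``mean_out``, ``effect`` (mean_in - mean_out), ``t``, ``df``, ``p``,
    ``q`` (BH across tested genes) and ``reason`` for untested genes.
    """
    in_lines = list(in_lines)
    out_lines = list(out_lines)
    overlap = set(in_lines) & set(out_lines)
    if overlap:
        raise ValueError(f"in/out groups overlap: {sorted(overlap)[:5]}")
    missing = [l for l in [*in_lines, *out_lines] if l not in dep.columns]
    if missing:
        raise ValueError(f"lines absent from dependency matrix: {missing[:5]}")

    a = dep[in_lines].to_numpy(dtype=float)
    b = dep[out_lines].to_numpy(dtype=float)
    genes = dep.index

    n_in = np.empty(len(genes), dtype=int)
    n_out = np.empty(len(genes), dtype=int)
    mean_in = np.empty(len(genes))
    mean_out = np.empty(len(genes))
    ss = np.empty(len(genes))
    for i in range(len(genes)):
        n_in[i], mean_in[i], ss_a = _group_stats(a[i])
        n_out[i], mean_out[i], ss_b = _group_stats(b[i])
        ss[i] = (ss_a if n_in[i] else np.nan) + (ss_b if n_out[i] else np.nan)

    tested = (n_in >= 2) & (n_out >= 2)
    d_g = np.where(tested, n_in + n_out - 2, np.nan).astype(float)
    s_sq = np.where(tested, ss / d_g, np.nan)
    effect = mean_in - mean_out

    if moderation is None:
        moderation = fit_moderation(s_sq[tested], d_g[tested])
    d0, s0_sq = moderation.d0, moderation.s0_sq

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s_tilde_sq = np.where(tested, s0_sq, np.nan)
            df_total = np.where(tested, np.inf, np.nan)
        else:
            s_tilde_sq = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
            df_total = d0 + d_g
        se = np.sqrt(s_tilde_sq * (1.0 / n_in + 1.0 / n_out))
        t = effect / se

    # Degenerate genes: zero moderated variance. Zero effect -> t=0, p=1;
    # nonzero effect -> the p-value underflows and the gene is flagged.
    zero_se = tested & (se == 0)
    t[zero_se & (effect == 0)] = 0.0
    p = np.full(len(genes), np.nan)
    fin = tested & np.isfinite(t)
    inf_df = fin & np.isinf(df_total)
    p[fin & ~inf_df] = 2.0 * stats.t.sf(np.abs(t[fin & ~inf_df]), df_total[fin & ~inf_df])
    p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    p[zero_se & (effect != 0)] = np.nextafter(0.0, 1.0)
    t[zero_se & (effect != 0)] = np.sign(effect[zero_se & (effect != 0)]) * np.inf

    q = bh_adjust(p)

    reason = np.where(
        tested,
        "",
        np.where(n_in < 2, "fewer than 2 non-missing in-group values",
                 "fewer than 2 non-missing out-group values"),
    )
    flags = np.where(zero_se & (effect != 0), "zero variance with nonzero effect", reason)

    out = pd.DataFrame(
        {
            "n_in": n_in,
            "n_out": n_out,
            "mean_in": mean_in,
            "mean_out": mean_out,
            "effect": effect,
            "t": t,
            "df": df_total,
            "p": p,
            "q": q,
            "reason": flags,
        },
        index=genes,
    )
    out.attrs["moderation"] = moderation
    return out
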