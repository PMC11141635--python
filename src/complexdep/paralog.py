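"""Paralog-redundancy screening via dependency-expression correlation.

Buffering between paralogs (the KAT2A/KAT2B pattern) shows up in screen
data as a dependency that manifests only where the partner is lowly
expressed. The screen here: select the cell lines dependent on an anchor
gene (gene-effect score below a threshold, default -0.3), then correlate a
query gene's dependency with genome-wide expression across those lines.
A redundant paralog surfaces as a strong negative Pearson association:
the lower its expression, the deeper the query dependency.

Significance uses the exact t-transform of the Pearson r,
t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 df, two-sided; the equivalent
one-predictor OLS F-test (F = t^2) is provided for single-pair checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffdep import bh_adjust

__all__ = [
    "CorrelationHit",
    "select_dependent_lines",
    "expression_dependency_screen",
    "linear_association_ftest",
    "DEPENDENCY_THRESHOLD",
]

# Gene-effect scores below this estimate growth inhibition/death on knockout.
DEPENDENCY_THRESHOLD = -0.3


@dataclass(frozen=True)
class CorrelationHit:
    """One gene's dependency-expression correlation across selected lines."""

    gene: str
    n: int
    r: float
    t: float
    p: float
    q: float = np.nan
    skipped: str | None = None


def select_dependent_lines(
    dep: pd.DataFrame, anchor_gene: str, threshold: float = DEPENDENCY_THRESHOLD
) -> list[str]:
    """Cell lines whose anchor-gene score is strictly below the threshold.

    Missing anchor scores never qualify. An empty selection is returned
    with a warning rather than raised, mirroring screens where no line
    depends on the anchor.
    """
    if anchor_gene not in dep.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in dependency matrix")
    row = dep.loc[anchor_gene]
    selected = [str(c) for c in dep.columns if pd.notna(row[c]) and row[c] < threshold]
    if not selected:
        warnings.warn(
            f"no lines with {anchor_gene} score < {threshold}", RuntimeWarning, stacklevel=2
        )
    return selected


def _pearson_with_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r with its exact t-statistic and two-sided p on n-2 df."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # exactly collinear up to float rounding
        r = float(np.sign(r))
        return r, r * np.inf, np.nextafter(0.0, 1.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(t), float(p)


def expression_dependency_screen(
    dep: pd.DataFrame,
    expr: pd.DataFrame,
    query_gene: str,
    lines: Sequence[str],
    expressed_only: bool = True,
    min_expression: float = 1.0,
) -> list[CorrelationHit]:
    """Correlate a query gene's dependency with every gene's expression.

    Parameters
    ----------
    dep, expr
        Genes × lines dependency and log2(TPM+1) expression matrices.
    query_gene
        Gene whose dependency vector anchors the correlations.
    lines
        Cell lines over which to correlate (typically from
        :func:`select_dependent_lines`).
    expressed_only
        Restrict to expressed genes, defined as max log2(TPM+1) >=
        ``min_expression`` across the selected lines.

    Returns per tested gene the Pearson r over pairwise-complete
    observations, its t-statistic and two-sided p (n-2 df), and BH q across
    all tested genes. Genes with < 3 paired values or a constant vector are
    emitted with ``skipped`` set. Results are sorted by ascending p.
    """
    if query_gene not in dep.index:
        raise KeyError(f"query gene {query_gene!r} not in dependency matrix")
    lines = [l for l in lines if l in dep.columns and l in expr.columns]
    if len(lines) < 3:
        raise ValueError("need >=3 selected lines present in both matrices")
    y_all = dep.loc[query_gene, lines].to_numpy(dtype=float)

    candidates = expr.loc[:, lines]
    if expressed_only:
        candidates = candidates[candidates.max(axis=1, skipna=True) >= min_expression]

    hits: list[CorrelationHit] = []
    for gene, row in candidates.iterrows():
        x = row.to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y_all)
        n = int(ok.sum())
        if n < 3:
            hits.append(CorrelationHit(str(gene), n, np.nan, np.nan, np.nan,
                                       skipped="fewer than 3 paired observations"))
            continue
        xs, ys = x[ok], y_all[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            hits.append(CorrelationHit(str(gene), n, np.nan, np.nan, np.nan,
                                       skipped="constant vector"))
            continue
        r, t, p = _pearson_with_t(xs, ys)
        hits.append(CorrelationHit(str(gene), n, r, t, p))

    ps = [h.p for h in hits]
    qs = bh_adjust(ps)
    hits = [
        CorrelationHit(h.gene, h.n, h.r, h.t, h.p, float(q) if np.isfinite(q) else np.nan,
                       h.skipped)
        for h, q in zip(hits, qs)
    ]
    hits.sort(key=lambda h: (np.inf if np.isnan(h.p) else h.p, h.gene))
    return hits


def linear_association_ftest(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float, float]:
    """OLS y ~ x association: (slope, F, p) with F = t_slope^2 on (1, n-2) df.

    The p-value is identical to the Pearson-correlation p on the same data.
    A constant y gives slope 0, F 0, p 1; a constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >=3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    r = max(-1.0, min(1.0, res.rvalue))
    n = x.size
    if abs(r) == 1.0:
        return float(res.slope), np.inf, np.nextafter(0.0, 1.0)
    t_sq = r * r * (n - 2) / (1.0 - r * r)
    p = float(stats.f.sf(t_sq, 1, n - 2))
    return float(res.slope), float(t_sq), p
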