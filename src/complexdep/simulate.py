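"""Synthetic screen and region fixtures with the structure the analysis assumes.

:func:`generate_screen` emulates a DepMap-style CRISPR screen release:

* gene-effect scores with the canonical bimodal structure — common-essential
  genes centered at -1 in every line, non-essential genes centered at 0,
  Gaussian noise around the class center (two-component mixture per gene
  class, so per-gene medians are testable);
* embedded subgroup-selective complexes: the member genes of each embedded
  complex are shifted by -effect_size in the target subgroup's lines only,
  the signal the differential-dependency -> enrichment arm must recover;
* decoy gene sets drawn uniformly from non-essential genes;
* per-line MYCN copy-number/expression/reported-status profiles spanning all
  four classifier regimes, including the exact 1.10 / 3 / 5 boundaries;
* optional redundant paralog pairs: the query gene's dependency deepens
  linearly as the partner's expression decreases, the Fig-6-style negative
  dependency-expression association.

:func:`generate_region_fixture` builds ChIP-style region × sample count and
AUC tables with configurable fold-change effect regions and per-sample
spike-in counts.

Both generators are fully determined by their seed (NumPy PCG64 via
``np.random.default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSetCollection

__all__ = [
    "LineageSpec",
    "EmbeddedComplex",
    "ParalogPair",
    "MycnProfile",
    "ScreenConfig",
    "ScreenBundle",
    "RegionFixture",
    "generate_screen",
    "generate_region_fixture",
    "default_mycn_profiles",
]


class ConfigError(ValueError):
    """A generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class LineageSpec:
    """A lineage block of cell lines; ``subgroup`` marks the target subgroup."""

    name: str
    n_lines: int
    subgroup: bool = False


@dataclass(frozen=True)
class EmbeddedComplex:
    """A gene set whose members are selectively depleted in the subgroup.

    effect_size is the downward shift (in score units) applied to every
    member gene in every target-subgroup line.
    """

    name: str
    members: tuple[str, ...]
    effect_size: float


@dataclass(frozen=True)
class ParalogPair:
    """A (query, partner) pair; when redundant, low partner expression deepens
    query dependency with the given slope (score units per log2(TPM+1))."""

    gene_a: str
    gene_b: str
    redundant: bool = True
    slope: float = 0.2


@dataclass(frozen=True)
class MycnProfile:
    """Per-line MYCN evidence: (log2(CN/2+1), log2(TPM+1), reported status)."""

    cn: float
    expr: float
    reported_status: str = "none"


@dataclass
class ScreenConfig:
    """Configuration of a synthetic screen; the seed fully determines output."""

    n_genes: int = 1000
    n_common_essential: int = 250
    lineages: tuple[LineageSpec, ...] = (
        LineageSpec("neuroblastoma", 20, subgroup=True),
        LineageSpec("other", 80),
    )
    essential_center: float = -1.0
    nonessential_center: float = 0.0
    noise_sd: float = 0.2
    embedded_complexes: tuple[EmbeddedComplex, ...] = ()
    n_decoy_sets: int = 30
    geneset_size_range: tuple[int, int] = (5, 15)
    mycn_profiles: tuple[MycnProfile, ...] | None = None  # None -> default regimes
    paralog_pairs: tuple[ParalogPair, ...] = ()
    expression_mean_range: tuple[float, float] = (1.0, 8.0)
    expression_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_common_essential <= 0:
            raise ConfigError("gene counts must be positive")
        if self.n_common_essential >= self.n_genes:
            raise ConfigError("need at least one non-essential gene")
        if not self.lineages or any(l.n_lines <= 0 for l in self.lineages):
            raise ConfigError("every lineage needs a positive line count")
        for c in self.embedded_complexes:
            if not np.isfinite(c.effect_size):
                raise ConfigError(f"complex {c.name!r}: effect size must be finite")
        if self.noise_sd < 0 or self.expression_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        lo, hi = self.geneset_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("invalid geneset_size_range")

    @property
    def n_lines(self) -> int:
        return sum(l.n_lines for l in self.lineages)


@dataclass
class ScreenBundle:
    """Everything the screen-analysis arm consumes, plus a truth block.

    ``truth`` records the embedded effects for recovery tests only; no
    analysis stage may read it.
    """

    dependency: pd.DataFrame        # genes x lines, Chronos-like scores
    expression: pd.DataFrame        # genes x lines, log2(TPM+1)
    copy_number: pd.Series          # per line, MYCN log2(CN/2+1)
    annotations: pd.DataFrame       # lineage, subgroup, MYCN evidence per line
    genesets: GeneSetCollection
    truth: dict = field(default_factory=dict)


# Canonical MYCN evidence templates: every classifier regime, with exact
# boundary cases at cn = 1.10, cn = 3 and expr = 5.
_AMPLIFIED_PROFILES = (
    MycnProfile(3.5, 7.0, "none"),          # rule 1
    MycnProfile(3.0, 6.0, "none"),          # rule 1 boundary (cn = 3)
    MycnProfile(4.0, 8.0, "amplified"),     # rule 1, concordant report
    MycnProfile(2.0, 6.0, "none"),          # rule 2
    MycnProfile(1.10, 5.0, "none"),         # rule 2, both boundaries
    MycnProfile(2.5, 4.0, "amplified"),     # rule 2 via report
)
_OTHER_PROFILES = (
    MycnProfile(2.0, 2.0, "none"),              # rule 3, low expression
    MycnProfile(2.5, 4.0, "not_amplified"),     # rule 3 via report
    MycnProfile(0.5, 0.5, "none"),              # no rule: undetermined
    MycnProfile(0.8, 2.0, "not_amplified"),     # no rule: undetermined
    MycnProfile(2.0, 4.0, "none"),              # expression gap: undetermined
    MycnProfile(3.5, 6.0, "not_amplified"),     # rule 1 inconsistent
    MycnProfile(0.5, 6.0, "not_amplified"),     # rule 4 inconsistent
)


def default_mycn_profiles(lineages: Sequence[LineageSpec]) -> list[MycnProfile]:
    """Assign MYCN evidence per line: amplified-regime profiles to subgroup
    lines, the remaining regimes (cycled) to all other lines."""
    profiles: list[MycnProfile] = []
    for spec in lineages:
        pool = _AMPLIFIED_PROFILES if spec.subgroup else _OTHER_PROFILES
        for i in range(spec.n_lines):
            profiles.append(pool[i % len(pool)])
    return profiles


def generate_screen(config: ScreenConfig) -> ScreenBundle:
    """Generate a deterministic synthetic :class:`ScreenBundle` from a config.

    Raises :class:`ConfigError` when an embedded complex or paralog pair
    references a gene outside the universe, or when an embedded complex
    targets a subgroup with zero lines.
    """
    rng = np.random.default_rng(config.seed)

    essential = [f"ESS{i:04d}" for i in range(config.n_common_essential)]
    n_non = config.n_genes - config.n_common_essential
    nonessential = [f"GENE{i:04d}" for i in range(n_non)]
    genes = essential + nonessential
    gene_set = set(genes)
    nonessential_set = set(nonessential)

    lines: list[str] = []
    lineage_col: list[str] = []
    subgroup_col: list[bool] = []
    for spec in config.lineages:
        for i in range(spec.n_lines):
            lines.append(f"{spec.name}_{i:03d}")
            lineage_col.append(spec.name)
            subgroup_col.append(spec.subgroup)
    subgroup_mask = np.array(subgroup_col)

    for c in config.embedded_complexes:
        unknown = set(c.members) - gene_set
        if unknown:
            raise ConfigError(f"complex {c.name!r} references unknown genes {sorted(unknown)}")
        if not subgroup_mask.any():
            raise ConfigError(f"complex {c.name!r} targets a subgroup with zero lines")
    for p in config.paralog_pairs:
        unknown = {p.gene_a, p.gene_b} - gene_set
        if unknown:
            raise ConfigError(f"paralog pair references unknown genes {sorted(unknown)}")

    n_genes, n_lines = len(genes), len(lines)

    # Dependency: class center + Gaussian noise; embedded members shifted
    # by -effect_size in subgroup lines.
    centers = np.where(
        np.arange(n_genes) < config.n_common_essential,
        config.essential_center,
        config.nonessential_center,
    )[:, None]
    dep = centers + rng.normal(0.0, config.noise_sd, size=(n_genes, n_lines))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for c in config.embedded_complexes:
        rows = [gene_idx[g] for g in c.members]
        dep[np.ix_(rows, np.nonzero(subgroup_mask)[0])] -= c.effect_size

    # Expression: per-gene mean, per-entry Gaussian noise, floored at 0.
    expr_means = rng.uniform(*config.expression_mean_range, size=n_genes)
    expr = expr_means[:, None] + rng.normal(0.0, config.expression_sd, size=(n_genes, n_lines))
    expr = np.clip(expr, 0.0, None)

    # Redundant paralogs: spread the partner's expression wide, then tie the
    # query's dependency to it (low partner expression -> deeper dependency).
    for p in config.paralog_pairs:
        if not p.redundant:
            continue
        bi, ai = gene_idx[p.gene_b], gene_idx[p.gene_a]
        expr[bi] = rng.uniform(0.0, 8.0, size=n_lines)
        link = p.slope * (expr[bi] - expr[bi].mean())
        dep[ai] = config.nonessential_center + link + rng.normal(
            0.0, config.noise_sd, size=n_lines
        )

    dependency = pd.DataFrame(dep, index=genes, columns=lines)
    expression = pd.DataFrame(expr, index=genes, columns=lines)
    dependency.index.name = expression.index.name = "gene"

    profiles = (
        list(config.mycn_profiles)
        if config.mycn_profiles is not None
        else default_mycn_profiles(config.lineages)
    )
    if len(profiles) < n_lines:
        profiles = [profiles[i % len(profiles)] for i in range(n_lines)]
    annotations = pd.DataFrame(
        {
            "lineage": lineage_col,
            "subgroup": subgroup_col,
            "mycn_cn": [p.cn for p in profiles[:n_lines]],
            "mycn_expr": [p.expr for p in profiles[:n_lines]],
            "reported_mycn_status": [p.reported_status for p in profiles[:n_lines]],
        },
        index=pd.Index(lines, name="line"),
    )
    copy_number = annotations["mycn_cn"].rename("mycn_cn")

    genesets = GeneSetCollection()
    for c in config.embedded_complexes:
        genesets.add(c.name, c.members, "embedded complex")
    lo, hi = config.geneset_size_range
    non_arr = np.array(nonessential)
    for i in range(config.n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(non_arr))
        members = rng.choice(non_arr, size=size, replace=False)
        genesets.add(f"DECOY{i:03d}", [str(g) for g in members], "decoy set")

    truth = {
        "embedded_complexes": config.embedded_complexes,
        "paralog_pairs": config.paralog_pairs,
        "essential_genes": tuple(essential),
        "nonessential_genes": tuple(nonessential),
        "subgroup_lines": tuple(np.array(lines)[subgroup_mask]),
        "mycn_profiles": tuple(profiles[:n_lines]),
    }
    return ScreenBundle(dependency, expression, copy_number, annotations, genesets, truth)


@dataclass
class RegionFixture:
    """Region × sample counts and AUC signal with per-sample spike-in counts."""

    regions: pd.DataFrame      # chrom/start/end/name
    counts: pd.DataFrame       # region x sample, integer read counts
    aucs: pd.DataFrame         # region x sample, AUC signal
    spikein: pd.Series         # per-sample dm6 counts
    groups: dict[str, list[str]]
    truth: dict = field(default_factory=dict)


def generate_region_fixture(
    n_regions: int,
    n_treated: int = 3,
    n_control: int = 3,
    effect_regions: Mapping[int, float] | None = None,
    baseline_mean: float = 1000.0,
    dispersion: float = 0.05,
    noise: bool = True,
    auc_per_read: float = 4.0,
    spikein_counts: Sequence[int] | None = None,
    seed: int | None = 0,
) -> RegionFixture:
    """Generate a ChIP-style region fixture.

    ``effect_regions`` maps region indices to the fold-change applied to the
    treated condition's expected signal; every other region exchanges only
    noise. With ``noise=False`` the counts equal their expected means
    exactly, so an effect region's treated/control ratio equals its fold
    change. Counts are negative-binomial around per-region baselines
    (Poisson when ``dispersion`` is 0); AUC is ``auc_per_read`` per read.
    """
    if n_treated + n_control <= 0:
        raise ConfigError("need at least one sample")
    if n_treated < 1 or n_control < 1:
        raise ConfigError("each condition needs at least one sample")
    if n_regions < 1:
        raise ConfigError("need at least one region")
    effect_regions = dict(effect_regions or {})
    bad = [i for i in effect_regions if not (0 <= i < n_regions)]
    if bad:
        raise ConfigError(f"effect region indices out of range: {bad}")

    rng = np.random.default_rng(seed)
    names = [f"region_{i:04d}" for i in range(n_regions)]
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_regions) * 2000,
            "end": np.arange(n_regions) * 2000 + 1000,
            "name": names,
        }
    )
    treated = [f"treated_{i}" for i in range(n_treated)]
    control = [f"control_{i}" for i in range(n_control)]
    samples = treated + control

    base = (
        rng.uniform(0.5, 1.5, size=n_regions) * baseline_mean
        if noise
        else np.full(n_regions, baseline_mean)
    )
    fold = np.ones(n_regions)
    for i, f in effect_regions.items():
        fold[i] = f
    mean = np.empty((n_regions, len(samples)))
    mean[:, :n_treated] = (base * fold)[:, None]
    mean[:, n_treated:] = base[:, None]

    if not noise:
        counts = mean.copy()
    elif dispersion <= 0:
        counts = rng.poisson(mean).astype(float)
    else:
        r = 1.0 / dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        counts = rng.poisson(lam).astype(float)

    counts_df = pd.DataFrame(counts, index=names, columns=samples)
    aucs = counts_df * auc_per_read

    if spikein_counts is None:
        spike = rng.integers(50_000, 150_000, size=len(samples)).astype(float)
    else:
        spike = np.asarray(list(spikein_counts), dtype=float)
        if spike.size != len(samples):
            raise ConfigError(
                f"spikein_counts length {spike.size} != {len(samples)} samples"
            )
    if (spike <= 0).any():
        raise ConfigError("spike-in counts must be positive")
    spikein = pd.Series(spike, index=samples, name="dm6_count")

    truth = {"effect_regions": effect_regions, "baseline": base, "fold": fold}
    return RegionFixture(
        regions=regions,
        counts=counts_df,
        aucs=aucs,
        spikein=spikein,
        groups={"treated": treated, "control": control},
        truth=truth,
    )
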