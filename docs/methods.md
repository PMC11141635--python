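# Methods

This note records the statistical models behind `complexdep`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter for reproducing its output.

## Screen model and the synthetic generator

The analysis assumes DepMap-style inputs: a genes × cell-lines matrix of
gene-effect scores in the Chronos/CERES convention (common-essential genes at a
median of −1 in every line, non-essential genes at 0, scores < −0.3 indicating
a fitness dependency), a log₂(TPM+1) expression matrix on the same axes, and
per-line annotations (lineage, MYCN copy number log₂(CN/2+1), expression,
reported status).

`generate_screen` emulates exactly that structure:

* **Score model.** Each gene belongs to one class (common-essential or
  non-essential); entries are the class center plus i.i.d. Gaussian noise. The
  mixture is per gene class, not per cell, so per-gene medians are testable
  against the class centers. Default noise SD is 0.2 score units — the
  dispersion of real gene-effect scores around their class centers is not
  pinned by the score convention itself, so this default is an arbitrary but
  fixed choice; it puts the false-dependency rate of a null gene
  (P(score < −0.3)) at ≈ 6.7%, a realistic single-digit rate. A heavier-tailed
  noise option was deliberately deferred.
* **Embedded selective complexes.** Member genes of an embedded complex are
  shifted by −effect_size in every target-subgroup line. With noise 0 the shift
  is exact, which pins the generator's arithmetic in tests.
* **Gene sets.** Each embedded complex becomes a gene set; decoy sets are drawn
  uniformly from non-essential genes (size uniform in 5–15 by default),
  mimicking complex collections where most sets carry no subgroup signal.
* **MYCN evidence.** Default per-line profiles cycle through fixed templates
  covering all four classifier regimes, including the exact boundary values
  cn = 1.10, cn = 3 and expr = 5, so classifier boundary behavior is always
  exercised. Subgroup lines get amplified-regime profiles.
* **Paralog buffering.** For a redundant pair (A, B), B's expression is spread
  uniformly over 0–8 log₂(TPM+1) and A's dependency is
  `center + slope·(exprB − mean) + noise` with positive slope, so low partner
  expression deepens the dependency — the negative-buffering geometry the
  correlation screen must recover. Default slope 0.2 score units per
  log₂(TPM+1) makes the partner detectable but not degenerate.
* **Determinism.** All draws come from one `numpy.random.default_rng(seed)`
  (PCG64); the same config and seed reproduce the bundle bit-for-bit on any
  platform.

What the generator does **not** emulate: guide-level counts and the
Chronos/CERES fit itself, screen batch effects and copy-number artifacts,
lineage-correlated expression programs, and realistic gene-gene covariance.
Passing recovery tests therefore demonstrate that the pipeline's statistics
detect the modeled signal geometry at realistic effect sizes and noise — not
that real screens are free of the confounders the generator omits.

The ChIP fixture (`generate_region_fixture`) draws region baselines uniformly
within ±50% of a mean depth, applies configured fold changes to the treated
condition, and adds gamma-Poisson (NB) count noise at a common dispersion
(default 0.05); AUC signal is proportional to counts. It emulates count/AUC
tables after alignment and peak calling, not reads or coverage profiles.

## Differential dependency

The two-class contrast uses a pooled-variance linear-model t with
empirical-Bayes variance moderation — the standard construction for the
limma-style model this analysis family relies on. Welch-type testing was
considered and rejected as the default to match that family; the pooled model
is also what the moderation theory assumes. The prior (d₀, s₀²) is estimated by
the method of moments on log s²_g using digamma/trigamma identities, with
trigamma inversion by Newton iteration; when the observed log-variances are no
more dispersed than sampling alone predicts (common on homoscedastic synthetic
data), the estimator returns the d₀ = ∞ limit — every variance shrunk to
s₀² — with a warning. The implementation reproduces `limma::eBayes` prior
estimates and moderated t/p to ~1e−8 on a shared fixture (see the test suite),
and reduces exactly to the classical pooled t at d₀ = 0.

Degenerate genes: zero pooled variance with zero effect yields t = 0, p = 1;
zero variance with a nonzero effect would divide by zero, so p is set to the
smallest positive float and the gene is flagged. Missing values are removed per
gene per group; a gene with fewer than two usable values in either group is
reported with NaN statistics and a reason rather than dropped.

## Enrichment statistics

`gsea_preranked` implements the weighted-KS running-sum statistic with weight
exponent p = 1 (the "weighted" scheme that is the cited software's default;
p = 0 gives the classic KS form and is exposed). The null is gene-label
permutation — random same-size sets — which is the only null available for a
preranked list; defaults are 1000 permutations and an explicit seed. NES
normalizes ES by the mean |same-sign permutation ES|; a set with no same-sign
permutations gets missing NES rather than 0. The nominal p is the one-sided
frequency of same-sign permutation ESs at least as extreme as the observed ES
(the convention of the reference GSEA software; note that a p computed over
*all* permutations regardless of sign would differ by roughly the same-sign
fraction). FDR follows the global same-sign NES-tail-ratio scheme; because that
pooled tail is coarse under few permutations, `fdr_method="auto"` switches to
BH on nominal p below 500 permutations.

Ranking is by descending score with lexicographic tie-breaks on gene id, so a
ranked list is a pure function of its scores. NaN scores are excluded and
counted.

`ssgsea_score` uses exponent α = 0.25 and global range normalization — the
published defaults of the single-sample method, which the upstream analysis
names without parameters. Weights use average ranks under ties; list positions
use the lexicographic order. The score is the *integral* (sum over all list
positions) of the in-set-minus-out-set ECDF difference, not an extremum.
Z-scores across samples use the sample SD (ddof = 1); constant sets get all-zero
z with a warning. Whether z-standardization should run over all screened lines
or a lineage subset is analysis-dependent, so the sample axis is simply
whatever columns the caller passes.

Overlap significance: hypergeometric upper tail P(X ≥ k) for hit-list vs set
overlap, and the two-tailed Fisher exact test (summing all tables with point
probability ≤ observed) for 2×2 contingency — both delegated to scipy's exact
routines.

## Paralog screen

Lines are selected by a strict `score < threshold` inequality (default −0.3,
the conventional dependency cutoff). The screen restricts to expressed genes —
max log₂(TPM+1) ≥ 1 across the selected lines — by default, mirroring the
expressed-gene definition used upstream; the filter is a flag because the
choice between all genes and expressed genes is not forced by the method.
Correlations use pairwise-complete observations per gene; constant vectors and
n < 3 are reported as skipped. Perfect collinearity (|r| within 1e−12 of 1) is
clamped to ±1 with the p-value at the smallest positive float, flagged by the
infinite t. BH q-values are computed across the whole screen; the t-cutoff
p ≤ 0.01 and the q filter are both left to the caller.

## ChIP-seq region stages

* **Scale factors.** factor_s = mean(dm6 counts)/dm6_s. The invariant — after
  multiplication every sample's spike-in total equals the pre-scaling mean — is
  exact by construction and tested to machine precision.
* **Curation.** The coverage gate keeps regions with log₂(AUC+1) ≥ 13
  (boundary retained: AUC = 8191 ⇒ log₂(8192) = 13 stays); the blacklist gate
  removes any region overlapping a blacklist interval by ≥ 1 bp — "overlap"
  with no minimum is the strictest reading and the conventional one. Curation
  runs on scaled AUC (scale → curate); the opposite order would make the fixed
  threshold depth-dependent.
* **Differential classification.** The effect measure Δ is the difference of
  condition means of log₂(AUC+1): a fixed ±1.5 cutoff is only scale-free on a
  log scale, which fixes the interpretation. Significance comes from a
  negative-binomial likelihood-ratio test (χ²₁) on counts with a single common
  dispersion estimated across regions by the method of moments
  (median of (v−m)/m², floored at 0, Poisson in the limit) — a deliberate
  simplification of tagwise/trended-dispersion GLM machinery, chosen for
  tractability and transparency; an exact group-relabeling permutation test on
  mean log counts is provided for small designs (3 vs 3 has 20 relabelings, so
  its floor is p = 0.05). Spike-in/library differences enter as mean offsets
  (μ_s = μ/factor_s). A region with all-zero counts is not_significant with
  p = 1. Both gates must pass: a region with |Δ| = 1.49 stays not_significant
  at any p.

## Validation problem sizes

The test suite and acceptance script run entirely on generated data at desk
scale: exhaustive enrichment-score checks on lists of length ≤ 12 with all
subsets of size ≤ 4; permutation agreement on 6-gene toys at 10,000
permutations; complex recovery on 500-gene × 100-line screens (20-line
subgroup, 8-gene complex at effect 0.6, 30 decoys) over 20 seeds with 300
permutations per enrichment run; null calibration on a 1000-gene screen; ChIP
classification on 3 vs 3 designs at ~1000-read depth. These sizes keep the full
suite under a minute while leaving every statistic in its asymptotically
honest regime (the recovery and calibration margins are not near their
thresholds).

## Known limitations

* The moderated-t design is the standard two-group contrast; arbitrary design
  matrices/contrasts are out of scope.
* GSEA FDR under few permutations falls back to BH on nominal p, which is more
  conservative than the pooled-NES scheme.
* The NB test's common dispersion underfits count heteroskedasticity across
  regions with strongly varying occupancy; the permutation option sidesteps
  the model at the cost of resolution.
* The generator's independence assumptions (genes, lines) understate the
  correlation structure of real screens; recovery rates on real data will be
  lower at equal effect sizes.
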