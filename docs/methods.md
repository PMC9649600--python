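# Methods

This note documents the statistical models implemented in `scnoise`, the
choices made where the procedure was genuinely open, and what the synthetic
validation does and does not establish.

## Quality control

A cell is removed when **any** of three criteria fails: fewer than 1000
endogenous genes detected (count ≥ 1, spike-ins excluded), fewer than
40,000 total mapped reads, or a spike-in read fraction above 0.74. The
source protocol's wording is ambiguous about the conjunction; the
any-failure reading is the only one under which each stated threshold is
individually binding, and it is what `qc_filter` implements. Total mapped
reads come from the metadata when supplied (the aligner's count) and
otherwise from the matrix column sums.

## Normalization

Size factors use the median-of-ratios construction: for each feature with
strictly positive counts in every cell, the reference is its geometric mean
across cells, and a cell's factor is the median ratio to that reference.
Factors are rescaled to geometric mean 1 so normalized totals stay on the
count scale. When no feature is positive everywhere, an opt-in `poscounts`
fallback uses a positive-part geometric-mean reference. Three feature
scopes are exposed — all features (the default, matching a naive
application to a matrix that carries spike-ins), endogenous-only, and
spike-in-only (needed to normalize the spike-ins on their own capture
scale). Expression is reported as `log2(count/s_j + pseudocount)` with
pseudocount 1 by default. TPM is provided for length-aware noise-trend
plots.

## Per-cell noise ratio (b/t)

Biological variation is `b = 1 − cor(x, u_group)` on log2-normalized
endogenous expression, technical variation `t = 1 − cor(x_spike, u_all)` on
log2-normalized spike-ins, both Pearson by default (Spearman by flag). The
spike-in mean vector is global (all QC-passing cells) rather than
group-wise, since spike-in capture does not depend on age. Endogenous genes
enter `b` only if detected in at least 5 cells (configurable) — correlations
over near-empty genes are dominated by the zero pattern. Cells with
`|t| < 1e-6` get an undefined ratio and are excluded from group tests with
a logged count. Group comparisons use two-sided Wilcoxon rank-sum tests
(exact for small untied samples).

Both `b` and `t` inherit Pearson's invariance under positive affine maps of
the expression vectors, which the tests assert numerically.

## Spike-in technical variance model and HVG test

Per spike-in species the normalized mean `μ` and squared coefficient of
variation `CV² = var/μ²` (unbiased variance, divisor m−1) are computed, and
`CV² = a1/μ + α0` is fitted by a gamma-family GLM with identity link —
the gamma variance function matches the approximately constant relative
error of a CV² estimate. Species below the 0.4 quantile of spike-in means
are excluded (their CV² estimates destabilize the GLM); `α0` is floored at
0; on GLM failure the model falls back to OLS of CV² on 1/μ, logged.

A gene with observed CV² among m cells is tested against the null that its
biological CV² does not exceed ω = 0.25:

    CV²_null = a1·ψ/μ + α0 + ω·(1 + α0)
    (m−1)·CV²/CV²_null  ~  χ²_(m−1)   (upper tail)

with BH correction per cell group. ψ is the spike-in/endogenous
size-factor cross-term; it defaults to 1, correct when one size-factor set
normalizes both feature classes, and is exposed as a knob for workflows
using separate spike-in factors. A gene is an HVG only when biological
CV² = CV² − (a1/μ + α0) exceeds ω **and** FDR < 0.1. Genes with zero mean
are excluded and counted. An optional exclusion list (e.g. cell-cycle
periodic genes) can be supplied; no list ships with the package.

The mean–CV² noise trend is an OLS fit of log10(CV²) on log10(mean) over
genes above an expression floor (default mean ≥ 1), reporting fitted CV² at
reference levels for between-group comparison. Under pure Poisson sampling
the slope is −1 and the intercept 0, which the validation suite verifies.

## Subgroups and generation correlations

The 16 h and 36 h groups are split at their arithmetic mean generation over
QC-passing cells; generation ≥ mean is fast-dividing (F), below is slow
(S). Ties at the mean go to F; the threshold is recorded in the output so
the choice is auditable. An all-equal generation vector is a degenerate
split and raises. Correlations with generation (genes detected, per-gene
expression, regulon summaries) are Pearson with the exact t transform on
n−2 degrees of freedom; Spearman is available by flag.

## Regulon screen

Per TF target set (≥ 5 mapped members; smaller sets are skipped and
logged):

1. **Median shift.** Per-cell summary = median log2-normalized expression
   over the TF's targets (mean by flag; the median mirrors the summary the
   shift is defined on). log2FC is the difference of subgroup means of
   these per-cell summaries — already a log2 fold change — tested with
   Welch's t. Pass: log2FC > 1 toward F and p < 0.01.
2. **Per-cell activity.** One-sided Wilcoxon rank-sum of the cell's
   detected targets against all its other detected genes; "on" at
   p < 1e−4 (at least 3 detected targets, else undefined). The null is
   enumerated exactly over all C(n, k) target placements when that count is
   ≤ 20,000 (valid under ties), otherwise a normal approximation with tie
   and continuity correction is used. Pass: the on-fraction is strictly
   greater in F than in S. This is the minimal aggregation rule consistent
   with intersecting per-cell calls; a stricter one-sided Fisher exact rule
   is available behind a flag.
3. **Generation coupling.** The per-cell target summary is correlated with
   generation within the age group. Pass: p < 0.05 and R > 0 (F-activation
   implies a positive slope, as F cells have higher generation).

The final hits are the order-stable intersection of the three pass sets.
Small target sets cannot reach the per-cell threshold (3 targets in 10
detected genes give at best p = 1/120), which is intentional stringency.

## Differential expression

Per gene, a negative-binomial GLM with a two-level group factor and
log-size-factor offsets. Gene-wise dispersion is estimated by bounded
maximum likelihood given the Poisson-fit means (method-of-moments
fallback), a parametric trend `α(μ) = a/μ + b` is fitted across genes
(gamma GLM, identity link), and gene-wise estimates are shrunk toward the
trend in log space with a fixed prior variance of 0.25 and a
trigamma-approximate sampling variance. The group coefficient's Wald z test
gives two-sided p-values, BH-adjusted over genes with nonzero counts;
significance requires |log2FC| > 1 and adjusted p < 0.05. When one group
has (nearly) no counts the Wald SE diverges; such genes fall back to a
0.5-count continuity-corrected group-mean estimate with a delta-method SE,
flagged as non-converged. This estimator is deliberately simple — no
independent filtering, no LFC shrinkage — and makes no claim of numerical
identity with external tools; the optional R bridge (`deseq2_bridge`)
reproduces exact DESeq2 output through a frozen subprocess script and
records the DESeq2 version.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
defaults fixed at the study conditions: 37/43/45 cells in the 2 h/16 h/36 h
groups; 92 spike-in species spanning five orders of magnitude of copy
number and summing to 8000 molecules per cell, captured Poisson with
per-cell efficiency (mean 0.25, sd 0.05 — at efficiency 0.25 a 10-copy
species is detected with probability 1 − e^(−2.5) ≈ 0.92, matching the
high detection expected above 10 copies); per-cell replicative generation
drawn as a shifted Poisson with group means 1/5/13 (only the ordering and
dispersion matter to the analyses); per-cell depth multipliers lognormal
(σ = 0.4) clipped to [0.25, 4]; gene means lognormal (median 15, log-sd
1.5) over 3000 genes; endogenous counts negative binomial (dispersion 0.1)
around mean × depth × extrinsic factor.

Design choices worth noting:

* **Extrinsic noise** is a per-gene, per-cell lognormal factor with
  group-specific scale (sd 0.1/0.3/0.5 on the natural-log scale) — the
  minimal mechanism that degrades a cell's correlation with its group mean
  without touching the spike-ins, so the b/t ratio rises with age by
  construction.
* **Unit-median noise factors.** All lognormal factors use log-mean 0, so
  the median-of-ratios size-factor estimator is unbiased for the designed
  depth multipliers; a unit-mean convention would bias the groups' factors
  against each other by e^(−σ²/2).
* **Spike-ins are Poisson, endogenous genes negative binomial** — the
  minimal pair under which the spike-in variance model is well-specified
  as a purely technical reference.
* **Markers.** A marker's log2 mean is coupled to generation with slope β
  chosen from the designed correlation r and the gene's noise budget
  (extrinsic variance plus log-scale sampling variance ln(1 + 1/μ + α),
  against the designed generation spread): β = r/√(1−r²) · σ_noise/σ_gen.
  Defaults plant correlations −0.6 and −0.4 in the 16 h group, the
  slow-divider iron-transport-marker pattern.
* **Regulon.** One TF set (default 60 targets) induced 2.5× in the
  fast-dividing cells of the 16 h group, plus 20 decoy sets of random
  genes; ground-truth subgroups use the same mean-generation split the
  pipeline applies.

What the generator does **not** emulate: the real data's dropout structure
(detection here is near-complete because designed gene means are rarely
≪ 1 per cell), gene–gene correlation beyond the planted regulon (extrinsic
factors are independent across genes, whereas real extrinsic noise is
shared within pathways), cell-cycle periodicity, amplification-length
biases, and batch effects. Passing the validation suite therefore
establishes correctness of the estimators under their own modelling
assumptions — not performance guarantees on any particular real dataset.

## Validation scenarios and problem sizes

The suite and the reproduction script run fixed scenarios chosen to keep a
full run in the order of seconds to a minute per scenario: the
Poisson-limit check on one default-size experiment (125 cells, 92 species);
HVG recovery on 20 replicates of 2000 genes × 45 cells with 200 planted
HVGs at biological CV² = 1 and mean ≥ 50; noise monotonicity and
size-factor recovery on one default experiment; marker recovery over 20
replicates; regulon recovery over 20 planted and 10 null replicates; and
40 randomized brute-force comparisons each for the exact rank-sum and
Pearson oracles. All randomness derives from a single seed via
`numpy.random.SeedSequence`, so runs are reproducible.

## Numerical details

* CV² uses the unbiased variance (divisor m−1) throughout.
* Tolerance for "t ≈ 0" in the noise ratio: 1e−6.
* BH adjustment via `statsmodels.stats.multitest.multipletests`.
* The gamma GLMs cap IRLS at 200 iterations and fall back to OLS on
  non-convergence or non-positive slope, logged.
* The exact rank-sum path switches to the normal approximation when
  C(n, k) > 20,000; with ~2000 detected genes per cell the approximation
  error is negligible relative to the 1e−4 activity threshold.
* Pipeline outputs are written with a fixed float format, so re-running
  with the same seed yields byte-identical files.

## Known limitations

* The NB Wald test is anti-conservative for very small groups (< 5 cells
  per side); the DESeq2 bridge is the reference in that regime.
* The HVG test conditions on the fitted technical model; uncertainty in
  (a1, α0) is not propagated, as in the standard formulation.
* The ψ cross-term default of 1 is only exact when a single size-factor
  set is used; analyses with separate spike-in factors should set it
  explicitly.
* The regulon screen's subgroup aggregation rule for approach 2 (strictly
  greater on-fraction in F) is the weakest defensible reading; the Fisher
  variant is stricter and will reduce hits.
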