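# scnoise

Spike-in-calibrated analysis of cell-to-cell transcriptional variability in
single-cell RNA-seq of replicatively aging budding yeast.

## The problem

Replicative aging in *Saccharomyces cerevisiae* is heterogeneous: isogenic
cells divide at different rates and reach different lifespans. Smart-seq2
profiling of single mother cells isolated at 2 h, 16 h and 36 h after birth
— each with its replicative generation recorded and a fixed pool of 8000
ERCC spike-in molecules (92 species) added at lysis — makes it possible to
ask whether transcriptional noise rises with age, which genes drive it, and
how slow- and fast-dividing cells differ. `scnoise` implements that full
analysis as a tested, reusable pipeline for anyone working with
spike-in-calibrated single-cell count data, together with a synthetic-data
generator with known ground truth for validating every stage.

## The statistics at its core

* **QC and normalization.** Cells are removed if they have fewer than 1000
  detected genes, fewer than 40,000 mapped reads, or a spike-in read
  fraction above 0.74. Per-cell size factors `s_j` use the median-of-ratios
  construction: `s_j = median_g(c_gj / (prod_k c_gk)^(1/m))` over genes
  positive in every cell, rescaled to geometric mean 1; expression is
  reported as `log2(c_gj / s_j + 1)`.
* **Per-cell noise ratio.** For cell *j* in age group *i*, biological
  variation `b_ij = 1 − cor(x_ij, u_i)` (endogenous profile vs group mean)
  and technical variation `t_ij = 1 − cor(x_contr_ij, u_contr)` (spike-in
  profile vs global spike-in mean). The ratio `b/t` expresses biological
  noise in technical-noise units; age groups are compared by Wilcoxon
  rank-sum tests.
* **Highly variable genes.** Spike-ins calibrate the technical variance
  model `CV² = a1/μ + α0` (gamma GLM, identity link). A gene with observed
  CV² among *m* cells is tested against the null that its biological CV²
  does not exceed ω = 0.25 via `(m−1)·CV²/CV²_null ~ χ²_(m−1)` with
  `CV²_null = a1·ψ/μ + α0 + ω(1+α0)`; HVGs need biological CV² > 0.25 and
  BH FDR < 0.1.
* **Slow/fast subgroups.** The 16 h and 36 h groups are split at their mean
  generation (ties go to F); gene expression is correlated with generation
  (Pearson, exact t transform).
* **Regulon screen.** Three stringent criteria are intersected per TF
  target set: (1) log2 fold change of the per-cell median target expression
  F vs S > 1 with Welch p < 0.01; (2) per-cell one-sided Wilcoxon rank-sum
  of targets vs all other detected genes, "on" at p < 1e−4, with a higher
  on-fraction in F than S; (3) target-summary–generation correlation with
  p < 0.05 and R > 0.
* **Differential expression.** Per-gene negative-binomial GLM with size-
  factor offsets, trend-shrunk dispersions and a Wald test; significance at
  |log2FC| > 1 and BH-adjusted p < 0.05. An optional subprocess bridge runs
  DESeq2 for exact reference results.

## Worked example

```python
import scnoise as sn

sim = sn.simulate_experiment(sn.SimulationDesign(), seed=1)
meta = sn.qc_filter(sim.counts, sim.meta)
print(f"QC: {int(meta.qc_pass.sum())}/{len(meta)} cells pass")

passing = meta[meta.qc_pass].reset_index(drop=True)
counts = sim.counts.subset_cells(passing.cell_id.tolist())
sf = sn.size_factors(counts)
norm = sn.normalize_log2(counts, sf)

noise = sn.cell_noise_ratio(norm, passing)
med = noise.groupby("age_group")["ratio"].median()
print("median b/t ratio:", {g: round(float(med[g]), 2) for g in ("2h", "16h", "36h")})
print("16h vs 36h Wilcoxon p =", f"{sn.compare_group_noise(noise, '16h', '36h')['p']:.2e}")

sf_spike = sn.size_factors(counts, feature_scope="spikein")
fit = sn.SpikeInNoiseModel(counts.spikeins(), sf_spike).fit()
print(fit.summary())

assign = sn.split_subgroups(passing, "16h")
comp = sn.compare_regulons(norm, passing, assign, sim.gene_sets, "16h")
print(comp.summary())
```

prints

```
QC: 125/125 cells pass
median b/t ratio: {'2h': 3.68, '16h': 4.66, '36h': 6.84}
16h vs 36h Wilcoxon p = 1.29e-09
Technical variance fit: CV^2 = a1/mu + alpha0
  a1        = 0.981384
  alpha0    = 0.000995073
  fit floor = 0.518755 (mean normalized expression)
  spike-ins = 50
  method    = glm-gamma
Regulon screen, 16h/S vs 16h/F:
  TFs tested        : 21
  approach 1 hits   : 1
  approach 1 & 2    : 1
  final (1 & 2 & 3) : 1 -> YAP1
```

The default simulation plants rising extrinsic noise across the three age
groups (the median b/t ratio climbs from 3.7 to 6.8), a near-Poisson
spike-in technical model (`a1 ≈ 1`, `α0 ≈ 0` in normalized units), and one
TF regulon induced 2.5× in the fast-dividing 16 h cells — which the
three-approach screen recovers as the sole final hit among 20 decoys.

The same stages are available from the shell via `scnoise run`,
`scnoise simulate`, `scnoise qc`, `scnoise normalize`, `scnoise hvg`,
`scnoise subgroups`, `scnoise regulon`, `scnoise de` and `scnoise trend`.

## Layout

```
src/scnoise/
  io.py          # containers and TSV/MTX/GMT/metadata readers
  config.py      # all stage thresholds (AnalysisConfig)
  qc.py          # QC filter, size factors, log2 normalization, TPM
  variability.py # b/t noise ratio, spike-in variance model, HVG test, trends
  aging.py       # S/F subgroup split, generation correlations
  regulon.py     # three-approach TF regulon screen
  diffexp.py     # NB Wald differential expression
  deseq2_bridge.py / deseq2_bridge.R  # optional exact DESeq2 runs
  synthetic.py   # ground-truth generator and recovery scoring
  scenarios.py   # fixed validation scenarios
  pipeline.py    # stage orchestration with manifest
  cli.py         # command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
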