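"""Synthetic aging scRNA-seq experiments with known ground truth.

The generator emulates the statistical structure the analysis stages
assume: a Smart-seq2-like experiment on single yeast cells sampled at 2h,
16h and 36h after birth (default 37/43/45 cells), with

* 92 ERCC spike-in species whose copy numbers span five orders of magnitude
  and sum to 8000 molecules per cell, captured as Poisson counts with a
  per-cell capture efficiency;
* endogenous genes drawn negative-binomially around gene mean x cell depth,
  multiplied by a per-gene, per-cell lognormal "extrinsic" factor whose
  scale grows with age group (the aging noise signal);
* planted highly variable genes with a designed biological CV^2;
* marker genes whose log expression is coupled to the cell's replicative
  generation so that the within-group expression-generation correlation
  matches a designed value (the slow-divider marker pattern);
* one planted TF regulon whose targets are induced by a designed fold
  change in the fast-dividing (F) cells of one age group, plus decoy TF
  sets with no effect.

All lognormal noise factors use log-mean 0 (unit median): the median-of-
ratios size-factor estimator is then unbiased for the designed per-cell
depth multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection, validate_spikein_table

_LN2 = np.log(2.0)


@dataclass
class SimulationDesign:
    """Parameters of one simulated experiment (defaults = study conditions)."""

    n_genes: int = 3000
    cells_per_group: dict[str, int] = field(
        default_factory=lambda: {"2h": 37, "16h": 43, "36h": 45}
    )
    generation_mean: dict[str, float] = field(
        default_factory=lambda: {"2h": 1.0, "16h": 5.0, "36h": 13.0}
    )
    extrinsic_sd: dict[str, float] = field(
        default_factory=lambda: {"2h": 0.1, "16h": 0.3, "36h": 0.5}
    )
    # spike-ins
    n_spikeins: int = 92
    spikein_total_molecules: float = 8000.0
    spikein_orders_of_magnitude: float = 5.0
    capture_efficiency_mean: float = 0.25
    capture_efficiency_sd: float = 0.05
    # per-cell depth (sequencing/capture scale of endogenous genes)
    depth_log_sd: float = 0.4
    depth_range: tuple[float, float] = (0.25, 4.0)
    # endogenous gene means
    gene_mean_median: float = 15.0
    gene_mean_log_sd: float = 1.5
    nb_dispersion: float = 0.1
    # planted highly variable genes
    n_hvgs: int = 150
    hvg_cv2: float = 1.0
    hvg_mean_range: tuple[float, float] = (50.0, 500.0)
    # generation-coupled marker genes
    marker_correlations: tuple[float, ...] = (-0.6, -0.4)
    marker_group: str = "16h"
    marker_base_mean: float = 50.0
    # planted regulon
    planted_tf: str | None = "YAP1"
    regulon_size: int = 60
    regulon_fold_change: float = 2.5
    regulon_group: str = "16h"
    n_decoy_tfs: int = 20
    decoy_size: int = 60

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_spikeins <= 0:
            raise ValueError("n_genes and n_spikeins must be positive")
        if any(n <= 0 for n in self.cells_per_group.values()):
            raise ValueError("cell counts must be positive")
        if self.nb_dispersion < 0 or self.hvg_cv2 < 0:
            raise ValueError("variances must be non-negative")
        sds = [self.extrinsic_sd[g] for g in self.cells_per_group if g in self.extrinsic_sd]
        if any(s < 0 for s in sds):
            raise ValueError("extrinsic sds must be non-negative")
        if not (0 < self.capture_efficiency_mean <= 1):
            raise ValueError("capture efficiency mean must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Everything needed to score pipeline output against the generator."""

    depth: pd.Series
    efficiency: pd.Series
    base_mean: pd.Series
    dispersion: float
    extrinsic_sd: dict[str, float]
    hvg_genes: list[str]
    hvg_cv2: float
    marker_genes: list[str]
    marker_correlations: tuple[float, ...]
    marker_beta: list[float]
    regulon_tf: str | None
    regulon_targets: list[str]
    regulon_fold_change: float
    regulon_group: str
    subgroup: pd.Series
    seed: int


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    meta: pd.DataFrame
    spikein_table: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: SimulationTruth


def spikein_molecule_design(
    n_species: int = 92,
    total: float = 8000.0,
    orders_of_magnitude: float = 5.0,
) -> pd.DataFrame:
    """Deterministic spike-in copy-number table (log-uniform, scaled sum)."""
    raw = np.geomspace(1.0, 10.0**orders_of_magnitude, n_species)
    molecules = raw * (total / raw.sum())
    ids = [f"ERCC-{i:05d}" for i in range(1, n_species + 1)]
    return validate_spikein_table(
        pd.DataFrame({"feature_id": ids, "molecules_per_cell": molecules}),
        expected_total=total,
    )


def _marker_beta(design: SimulationDesign, r: float) -> float:
    """Slope (log2 units/generation) inducing correlation r within the
    marker group, from the designed noise budget of the marker gene."""
    if not (-1 < r < 1):
        raise ValueError("designed correlation must be in (-1, 1)")
    if r == 0:
        return 0.0
    group = design.marker_group
    sigma_ext = design.extrinsic_sd.get(group, 0.0)
    cv2_sampling = 1.0 / design.marker_base_mean + design.nb_dispersion
    var_log = sigma_ext**2 + np.log1p(cv2_sampling)
    sd_log2 = np.sqrt(var_log) / _LN2
    sd_gen = np.sqrt(max(design.generation_mean[group] - 1.0, 0.25))
    return r / np.sqrt(1.0 - r * r) * sd_log2 / sd_gen


def simulate_experiment(design: SimulationDesign, seed: int = 0) -> SimulatedExperiment:
    """Draw one experiment; identical seeds give identical bundles."""
    rng = np.random.default_rng(seed)
    groups = list(design.cells_per_group)
    n_markers = len(design.marker_correlations)
    n_reserved = n_markers + design.n_hvgs
    if design.planted_tf is not None:
        n_reserved += design.regulon_size + design.n_decoy_tfs * design.decoy_size
    if n_reserved > design.n_genes:
        raise ValueError(
            f"design infeasible: {n_reserved} genes reserved for markers, HVGs "
            f"and regulons but only {design.n_genes} genes designed"
        )
    if n_markers and design.marker_group not in design.cells_per_group:
        raise ValueError(
            f"design infeasible: marker_group {design.marker_group!r} has no cells"
        )

    # --- cells -----------------------------------------------------------
    cell_ids, age_group, generation = [], [], []
    for g in groups:
        n = design.cells_per_group[g]
        lam = max(design.generation_mean[g] - 1.0, 0.0)
        gens = 1 + rng.poisson(lam, size=n)
        for i, gen in enumerate(gens):
            cell_ids.append(f"c{g}_{i + 1:03d}")
            age_group.append(g)
            generation.append(int(gen))
    cell_ids = np.asarray(cell_ids, dtype=object)
    age_group = np.asarray(age_group, dtype=object)
    generation = np.asarray(generation)
    n_cells = len(cell_ids)

    depth = np.clip(
        rng.lognormal(mean=0.0, sigma=design.depth_log_sd, size=n_cells),
        *design.depth_range,
    )
    efficiency = np.clip(
        rng.normal(design.capture_efficiency_mean, design.capture_efficiency_sd, n_cells),
        0.01,
        1.0,
    )

    # --- genes -----------------------------------------------------------
    gene_ids = np.array([f"gene_{i:05d}" for i in range(1, design.n_genes + 1)], dtype=object)
    base_mean = rng.lognormal(
        mean=np.log(design.gene_mean_median), sigma=design.gene_mean_log_sd,
        size=design.n_genes,
    )

    perm = rng.permutation(design.n_genes)
    marker_idx = perm[:n_markers]
    hvg_idx = perm[n_markers : n_markers + design.n_hvgs]
    rest = perm[n_markers + design.n_hvgs :]

    base_mean[marker_idx] = design.marker_base_mean
    if design.n_hvgs:
        lo, hi = design.hvg_mean_range
        base_mean[hvg_idx] = np.exp(rng.uniform(np.log(lo), np.log(hi), design.n_hvgs))

    # planted regulon + decoys among reasonably expressed untouched genes
    detectable = rest[base_mean[rest] >= 5.0]
    sets: dict[str, frozenset[str]] = {}
    regulon_idx = np.array([], dtype=int)
    if design.planted_tf is not None:
        need = design.regulon_size + design.n_decoy_tfs * design.decoy_size
        if len(detectable) < need:
            raise ValueError(
                f"design infeasible: {len(detectable)} detectable genes available, "
                f"{need} needed for regulon and decoy sets"
            )
        picked = rng.choice(detectable, size=need, replace=False)
        regulon_idx = picked[: design.regulon_size]
        sets[design.planted_tf] = frozenset(gene_ids[regulon_idx])
        for d in range(design.n_decoy_tfs):
            lo_i = design.regulon_size + d * design.decoy_size
            decoy = picked[lo_i : lo_i + design.decoy_size]
            sets[f"TF_DECOY_{d + 1:02d}"] = frozenset(gene_ids[decoy])
    gene_sets = GeneSetCollection(sets, source="synthetic")

    # --- ground-truth subgroups (split rule of the analysis) -------------
    subgroup = np.full(n_cells, "NA", dtype=object)
    for g in groups:
        if g == "2h":
            continue
        mask = age_group == g
        if mask.sum() >= 2 and np.ptp(generation[mask]) > 0:
            thr = generation[mask].mean()
            subgroup[mask] = np.where(generation[mask] >= thr, "F", "S")

    # --- endogenous mean matrix ------------------------------------------
    M = base_mean[:, None] * depth[None, :]

    betas: list[float] = []
    if n_markers:
        g_center = design.generation_mean[design.marker_group]
        for k, r in enumerate(design.marker_correlations):
            beta = _marker_beta(design, r)
            betas.append(beta)
            M[marker_idx[k], :] *= 2.0 ** (beta * (generation - g_center))

    if design.planted_tf is not None and design.regulon_fold_change != 1.0:
        f_cells = (age_group == design.regulon_group) & (subgroup == "F")
        M[np.ix_(regulon_idx, np.where(f_cells)[0])] *= design.regulon_fold_change

    # extrinsic (age-dependent) and planted-HVG lognormal factors
    lam = M.copy()
    for g in groups:
        sd = design.extrinsic_sd.get(g, 0.0)
        if sd > 0:
            mask = age_group == g
            lam[:, mask] *= rng.lognormal(0.0, sd, size=(design.n_genes, int(mask.sum())))
    if design.n_hvgs and design.hvg_cv2 > 0:
        sd_hvg = np.sqrt(np.log1p(design.hvg_cv2))
        lam[hvg_idx, :] *= rng.lognormal(0.0, sd_hvg, size=(design.n_hvgs, n_cells))

    if design.nb_dispersion > 0:
        shape = 1.0 / design.nb_dispersion
        lam = rng.gamma(shape=shape, scale=lam / shape)
    endo_counts = rng.poisson(lam)

    # --- spike-ins ---------------------------------------------------------
    spike_table = spikein_molecule_design(
        design.n_spikeins,
        design.spikein_total_molecules,
        design.spikein_orders_of_magnitude,
    )
    molecules = spike_table["molecules_per_cell"].to_numpy()
    spike_counts = rng.poisson(molecules[:, None] * efficiency[None, :])

    values = np.vstack([endo_counts, spike_counts])
    feature_ids = np.concatenate([gene_ids, spike_table["feature_id"].to_numpy()])
    counts = CountMatrix(values, feature_ids, cell_ids)

    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "age_group": age_group,
            "generation": generation,
            "total_mapped_reads": values.sum(axis=0),
        }
    )

    truth = SimulationTruth(
        depth=pd.Series(depth, index=cell_ids, name="depth"),
        efficiency=pd.Series(efficiency, index=cell_ids, name="efficiency"),
        base_mean=pd.Series(base_mean, index=gene_ids, name="base_mean"),
        dispersion=design.nb_dispersion,
        extrinsic_sd=dict(design.extrinsic_sd),
        hvg_genes=list(gene_ids[hvg_idx]),
        hvg_cv2=design.hvg_cv2,
        marker_genes=list(gene_ids[marker_idx]),
        marker_correlations=tuple(design.marker_correlations),
        marker_beta=betas,
        regulon_tf=design.planted_tf,
        regulon_targets=list(gene_ids[regulon_idx]),
        regulon_fold_change=design.regulon_fold_change,
        regulon_group=design.regulon_group,
        subgroup=pd.Series(subgroup, index=cell_ids, name="subgroup"),
        seed=seed,
    )
    return SimulatedExperiment(counts, meta, spike_table, gene_sets, truth)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth scores; ``checks`` maps name -> bool for the checks
    that carry a configured tolerance."""

    values: dict[str, float] = field(default_factory=dict)
    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.checks.values())

    def summary(self) -> str:
        lines = ["Recovery report:"]
        for name, value in self.values.items():
            verdict = ""
            if name in self.checks:
                verdict = "  [PASS]" if self.checks[name] else "  [FAIL]"
            lines.append(f"  {name:32s} {value:.4g}{verdict}")
        return "\n".join(lines)


def evaluate_recovery(
    truth: SimulationTruth,
    size_factors: pd.Series | None = None,
    hvg_frame: pd.DataFrame | None = None,
    noise_frame: pd.DataFrame | None = None,
    correlation_frame: pd.DataFrame | None = None,
    regulon_hits: list[str] | None = None,
    de_frame: pd.DataFrame | None = None,
    sf_tolerance: float = 0.05,
    hvg_sensitivity_min: float = 0.8,
    hvg_fdr_max: float = 0.15,
    marker_abs_error_max: float = 0.15,
) -> RecoveryReport:
    """Score any subset of pipeline outputs against the generator's truth."""
    report = RecoveryReport()

    if size_factors is not None:
        common = [c for c in size_factors.index if c in truth.depth.index]
        if not common:
            raise ValueError("no overlapping cells between size factors and truth")
        sf = size_factors.loc[common].to_numpy(dtype=float)
        d = truth.depth.loc[common].to_numpy(dtype=float)
        sf = sf / np.exp(np.mean(np.log(sf)))
        d = d / np.exp(np.mean(np.log(d)))
        err = float(np.median(np.abs(sf / d - 1.0)))
        report.values["size_factor_median_rel_error"] = err
        report.checks["size_factor_median_rel_error"] = err <= sf_tolerance

    if hvg_frame is not None:
        called = set(hvg_frame.loc[hvg_frame["is_hvg"], "gene"].astype(str))
        planted = set(truth.hvg_genes)
        tp = len(called & planted)
        sens = tp / len(planted) if planted else float("nan")
        fdr = (len(called) - tp) / len(called) if called else 0.0
        report.values["hvg_sensitivity"] = sens
        report.values["hvg_fdr"] = fdr
        report.checks["hvg_sensitivity"] = sens >= hvg_sensitivity_min
        report.checks["hvg_fdr"] = fdr <= hvg_fdr_max

    if noise_frame is not None:
        order = [g for g in ("2h", "16h", "36h") if g in set(noise_frame["age_group"])]
        medians = [
            float(noise_frame.loc[noise_frame["age_group"] == g, "ratio"].median())
            for g in order
        ]
        for g, m in zip(order, medians):
            report.values[f"noise_ratio_median_{g}"] = m
        increasing = all(b > a for a, b in zip(medians, medians[1:]))
        sds = [truth.extrinsic_sd[g] for g in order]
        if all(b > a for a, b in zip(sds, sds[1:])):
            report.checks["noise_ratio_monotone"] = increasing
            report.values["noise_ratio_monotone"] = float(increasing)

    if correlation_frame is not None and truth.marker_genes:
        marker = truth.marker_genes[0]
        frame = correlation_frame.set_index(correlation_frame["gene"].astype(str))
        if marker in frame.index:
            r_est = float(frame.loc[marker, "R"])
            rank = int((correlation_frame["R"] < r_est).sum()) + 1
            err = abs(r_est - truth.marker_correlations[0])
            report.values["marker_R"] = r_est
            report.values["marker_abs_error"] = err
            report.values["marker_negative_rank"] = rank
            report.checks["marker_abs_error"] = err <= marker_abs_error_max
        else:
            report.values["marker_R"] = float("nan")
            report.checks["marker_abs_error"] = False

    if regulon_hits is not None and truth.regulon_tf is not None:
        if truth.regulon_fold_change != 1.0:
            exact = regulon_hits == [truth.regulon_tf]
            report.values["regulon_exact_recovery"] = float(exact)
            report.checks["regulon_exact_recovery"] = exact
        else:
            report.values["regulon_null_hits"] = float(len(regulon_hits))
            report.checks["regulon_null_hits"] = len(regulon_hits) == 0

    if de_frame is not None and truth.regulon_targets:
        sig_up = set(
            de_frame.loc[
                (de_frame["significant"]) & (de_frame["log2FC"] > 0), "gene"
            ].astype(str)
        )
        recall = len(sig_up & set(truth.regulon_targets)) / len(truth.regulon_targets)
        report.values["de_planted_recall"] = recall

    return report
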