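"""Benchmark scenarios: fixed study-condition simulations with scoring.

Each function simulates data with the generator, runs the corresponding
analysis stage end to end, and returns measured quantities.  They are used
both by the validation suite and by the reproduction script; every number
they return is computed at call time.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .aging import gene_generation_correlation, split_subgroups
from .qc import normalize_log2, qc_filter, size_factors
from .regulon import compare_regulons, per_cell_regulon_activity
from .synthetic import SimulationDesign, simulate_experiment
from .variability import cell_noise_ratio, compare_group_noise, fit_technical_cv2, hvg_test, mean_cv2_trend


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def poisson_limit(seed: int = 0) -> dict:
    """Pure capture noise: NB dispersion 0, no extrinsic or planted signal.

    The spike-in noise trend must approach CV^2 = 1/mu (slope -1 on the
    log-log scale) and the technical fit's asymptotic offset must vanish.
    """
    design = SimulationDesign(
        nb_dispersion=0.0,
        extrinsic_sd={"2h": 0.0, "16h": 0.0, "36h": 0.0},
        n_hvgs=0,
        marker_correlations=(),
        planted_tf=None,
    )
    sim = simulate_experiment(design, seed=seed)
    sf_spike = size_factors(sim.counts, feature_scope="spikein")
    fit = fit_technical_cv2(sim.counts.spikeins(), sf_spike)
    spike_lin = sim.counts.spikeins().values / sf_spike.to_numpy()[None, :]
    trend = mean_cv2_trend(spike_lin, group="spikein", floor=1.0)
    return {"slope": trend.slope, "alpha0": fit.alpha0, "n_cells": sim.counts.n_cells}


def hvg_recovery(seed: int = 0, n_reps: int = 20) -> dict:
    """Planted-HVG recovery: 2000 genes, 200 planted at biological CV^2 = 1
    and mean >= 50, m = 45 cells; aggregated over replicates."""
    design = SimulationDesign(
        n_genes=2000,
        cells_per_group={"16h": 45},
        generation_mean={"16h": 5.0},
        extrinsic_sd={"16h": 0.0},
        nb_dispersion=0.0,
        n_hvgs=200,
        hvg_cv2=1.0,
        marker_correlations=(),
        planted_tf=None,
    )
    tp = fp = fn = 0
    sens = []
    for k in range(n_reps):
        sim = simulate_experiment(design, seed=_subseed(seed, k))
        sf_spike = size_factors(sim.counts, feature_scope="spikein")
        fit = fit_technical_cv2(sim.counts.spikeins(), sf_spike)
        sf = size_factors(sim.counts)
        out = hvg_test(sim.counts.endogenous(), sf, fit)
        called = set(out.loc[out["is_hvg"], "gene"].astype(str))
        planted = set(sim.truth.hvg_genes)
        tp_k = len(called & planted)
        tp += tp_k
        fp += len(called) - tp_k
        fn += len(planted) - tp_k
        sens.append(tp_k / len(planted))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": fp / max(tp + fp, 1),
        "n_reps": n_reps,
        "m_cells": 45,
    }


def noise_monotonicity(seed: int = 0) -> dict:
    """Default three-group design (extrinsic sd 0.1/0.3/0.5): the median
    b/t ratio must increase with age and the group differences test strong."""
    sim = simulate_experiment(SimulationDesign(), seed=seed)
    meta = qc_filter(sim.counts, sim.meta)
    sf = size_factors(sim.counts)
    norm = normalize_log2(sim.counts, sf)
    noise = cell_noise_ratio(norm, meta)
    order = ["2h", "16h", "36h"]
    medians = {g: float(noise.loc[noise["age_group"] == g, "ratio"].median()) for g in order}
    p_values = {
        f"{a}_vs_{b}": compare_group_noise(noise, a, b)["p"]
        for a, b in combinations(order, 2)
    }
    monotone = medians["2h"] < medians["16h"] < medians["36h"]
    return {
        "medians": medians,
        "max_pairwise_p": max(p_values.values()),
        "p_values": p_values,
        "monotone": monotone,
        "n_cells": len(noise),
    }


def size_factor_recovery(seed: int = 0) -> dict:
    """Median relative error of estimated size factors against the designed
    per-cell depth multipliers (range [0.25, 4])."""
    sim = simulate_experiment(SimulationDesign(), seed=seed)
    sf = size_factors(sim.counts, feature_scope="endogenous")
    d = sim.truth.depth.loc[sf.index].to_numpy()
    s = sf.to_numpy() / np.exp(np.mean(np.log(sf.to_numpy())))
    d = d / np.exp(np.mean(np.log(d)))
    return {
        "median_rel_error": float(np.median(np.abs(s / d - 1.0))),
        "n_cells": len(sf),
    }


def marker_recovery(seed: int = 0, n_reps: int = 20) -> dict:
    """Marker planted at expression-generation correlation -0.6 in the 16h
    group (n = 43): estimated R and its rank among most-negative genes."""
    rs = []
    top5 = 0
    for k in range(n_reps):
        sim = simulate_experiment(SimulationDesign(), seed=_subseed(seed, k))
        meta = qc_filter(sim.counts, sim.meta)
        sf = size_factors(sim.counts)
        norm = normalize_log2(sim.counts, sf)
        cor = gene_generation_correlation(norm, meta, "16h")
        marker = sim.truth.marker_genes[0]
        row = cor.set_index(cor["gene"].astype(str)).loc[marker]
        r_est = float(row["R"])
        rank = int((cor["R"] < r_est).sum()) + 1
        rs.append(r_est)
        top5 += rank <= 5
    return {
        "mean_R": float(np.mean(rs)),
        "designed_R": -0.6,
        "top5_rate": top5 / n_reps,
        "n_reps": n_reps,
    }


def regulon_recovery(seed: int = 0, n_reps: int = 20, n_null: int = 10) -> dict:
    """Planted regulon (2.5x in 16h/F) among 20 decoys: rate of exact final
    recovery; and rate of empty final hit lists under a null design."""
    exact = 0
    for k in range(n_reps):
        sim = simulate_experiment(SimulationDesign(), seed=_subseed(seed, 1000 + k))
        meta = qc_filter(sim.counts, sim.meta)
        passing = meta[meta["qc_pass"]].reset_index(drop=True)
        counts = sim.counts.subset_cells(passing["cell_id"].tolist())
        sf = size_factors(counts)
        norm = normalize_log2(counts, sf)
        assign = split_subgroups(passing, "16h")
        comp = compare_regulons(norm, passing, assign, sim.gene_sets, "16h")
        exact += comp.final_hits == [sim.truth.regulon_tf]
    null_design = SimulationDesign(regulon_fold_change=1.0)
    null_zero = 0
    for k in range(n_null):
        sim = simulate_experiment(null_design, seed=_subseed(seed, 2000 + k))
        meta = qc_filter(sim.counts, sim.meta)
        passing = meta[meta["qc_pass"]].reset_index(drop=True)
        counts = sim.counts.subset_cells(passing["cell_id"].tolist())
        sf = size_factors(counts)
        norm = normalize_log2(counts, sf)
        assign = split_subgroups(passing, "16h")
        comp = compare_regulons(norm, passing, assign, sim.gene_sets, "16h")
        null_zero += len(comp.final_hits) == 0
    return {
        "exact_recovery_rate": exact / n_reps,
        "null_zero_rate": null_zero / n_null,
        "n_reps": n_reps,
        "n_null": n_null,
    }


def exact_small_sample_oracles(seed: int = 0, n_cases: int = 40) -> dict:
    """Agreement of the fast statistics with brute-force references.

    Per-cell rank-sum p-values for cells with <= 12 detected genes are
    compared with an explicit enumeration over all target placements, and
    the Pearson-based biological variation b with the explicit sum formula.
    """
    rng = np.random.default_rng(seed)
    max_p_diff = 0.0
    from .io import GeneSetCollection
    from .qc import NormalizedMatrix

    for _ in range(n_cases):
        n = int(rng.integers(5, 13))
        k = int(rng.integers(2, max(3, n - 1)))
        values = rng.integers(1, 6, size=n).astype(float)
        ids = np.array([f"g{i}" for i in range(n)], dtype=object)
        norm = NormalizedMatrix(
            values[:, None], ids, np.array(["cell"], dtype=object),
            np.zeros(n, dtype=bool), 1.0,
        )
        targets = rng.choice(n, size=k, replace=False)
        sets = GeneSetCollection({"TF": frozenset(ids[targets])})
        table = per_cell_regulon_activity(norm, sets, min_targets=2)
        p_impl = float(table["p"].iloc[0])
        # brute force over all C(n, k) placements of the target ranks
        ranks = rankdata(values)
        w_obs = ranks[targets].sum()
        hits = total = 0
        for subset in combinations(range(n), k):
            total += 1
            if ranks[list(subset)].sum() >= w_obs - 1e-9:
                hits += 1
        max_p_diff = max(max_p_diff, abs(p_impl - hits / total))

    max_b_diff = 0.0
    for _ in range(n_cases):
        n_genes, n_cells = int(rng.integers(5, 20)), int(rng.integers(3, 8))
        values = rng.uniform(0.5, 9.0, size=(n_genes, n_cells))
        ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
        cells = np.array([f"c{j}" for j in range(n_cells)], dtype=object)
        norm = NormalizedMatrix(values, ids, cells, np.zeros(n_genes, bool), 1.0)
        spikes = NormalizedMatrix(
            rng.uniform(0.5, 9.0, size=(4, n_cells)),
            np.array([f"ERCC-{i:05d}" for i in range(4)], dtype=object),
            cells, np.ones(4, bool), 1.0,
        )
        full = NormalizedMatrix(
            np.vstack([norm.values, spikes.values]),
            np.concatenate([norm.feature_ids, spikes.feature_ids]),
            cells,
            np.concatenate([norm.is_spikein, spikes.is_spikein]),
            1.0,
        )
        meta = pd.DataFrame({"cell_id": cells, "age_group": "16h", "generation": 5})
        noise = cell_noise_ratio(full, meta, min_detect_cells=1)
        u = values.mean(axis=1)
        for j, cell in enumerate(cells):
            x = values[:, j]
            m = n_genes
            sx, su = x.sum(), u.sum()
            sxu, sxx, suu = (x * u).sum(), (x * x).sum(), (u * u).sum()
            r_ref = (m * sxu - sx * su) / np.sqrt((m * sxx - sx * sx) * (m * suu - su * su))
            b_ref = 1.0 - r_ref
            b_impl = float(noise.loc[noise["cell_id"] == cell, "b"].iloc[0])
            max_b_diff = max(max_b_diff, abs(b_impl - b_ref))
    return {
        "max_wilcoxon_p_abs_diff": max_p_diff,
        "max_pearson_b_abs_diff": max_b_diff,
        "n_cases": n_cases,
    }
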