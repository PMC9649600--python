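"""End-to-end orchestration: qc -> normalize -> variability -> subgroups ->
regulon -> differential expression, with TSV outputs and a JSON manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aging import SPLITTABLE_GROUPS, gene_generation_correlation, genes_detected_generation_cor, split_subgroups
from .config import AnalysisConfig
from .diffexp import nb_wald_de
from .io import (
    CountMatrix,
    GeneSetCollection,
    ValidationError,
    read_cell_meta,
    read_counts,
    read_gene_sets,
)
from .qc import normalize_log2, qc_filter, size_factors
from .regulon import compare_regulons
from .variability import cell_noise_ratio, compare_group_noise, fit_technical_cv2, hvg_test, mean_cv2_trend

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(
    config: AnalysisConfig,
    counts: CountMatrix,
    meta: pd.DataFrame,
    gene_sets: GeneSetCollection | None,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute every stage in order and write results under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).  Any stage
    failure aborts with the stage name and cause.  Given the same inputs and
    seed the numeric outputs are identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    manifest: dict = {
        "package": "scnoise",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def stage_done(name: str, **counts_out) -> None:
        manifest["stages"].append({"name": name, **counts_out})

    # ---- qc ---------------------------------------------------------------
    try:
        meta = qc_filter(counts, meta, config)
        _write(
            meta[
                ["cell_id", "age_group", "generation", "genes_detected",
                 "total_mapped_reads", "ercc_fraction", "qc_pass"]
            ],
            outdir / "qc_metrics.tsv",
        )
        stage_done("qc", n_cells_in=len(meta), n_cells_pass=int(meta["qc_pass"].sum()))
    except Exception as exc:
        raise PipelineError("qc", exc) from exc

    # ---- normalize ---------------------------------------------------------
    try:
        passing = meta.loc[meta["qc_pass"], "cell_id"].tolist()
        if not passing:
            raise ValidationError("no cells pass QC")
        counts_qc = counts.subset_cells(passing)
        meta_qc = meta[meta["qc_pass"]].reset_index(drop=True)
        sf = size_factors(counts_qc, feature_scope=config.size_factor_scope)
        sf_spike = size_factors(counts_qc, feature_scope="spikein")
        norm = normalize_log2(counts_qc, sf, config.pseudocount)
        sf.rename("size_factor").to_frame().assign(cell_id=sf.index)[
            ["cell_id", "size_factor"]
        ].to_csv(outdir / "size_factors.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        norm.to_frame().to_csv(outdir / "normalized_log2.tsv", sep="\t", float_format=_FLOAT_FMT)
        stage_done("normalize", n_cells=len(passing), n_features=counts_qc.n_features)
    except Exception as exc:
        raise PipelineError("normalize", exc) from exc

    # ---- variability -------------------------------------------------------
    try:
        noise = cell_noise_ratio(
            norm, meta_qc, min_detect_cells=config.noise_min_detect_cells,
            t_tolerance=config.t_tolerance,
        )
        _write(noise, outdir / "noise_per_cell.tsv")
        groups = [g for g in ("2h", "16h", "36h") if (meta_qc["age_group"] == g).sum() >= 3]
        comparisons = [
            compare_group_noise(noise, a, b)
            for a, b in zip(groups, groups[1:])
        ]
        _write(pd.DataFrame(comparisons), outdir / "noise_group_tests.tsv")

        hvg_counts = {}
        fits = {}
        for g in groups:
            cells_g = meta_qc.loc[meta_qc["age_group"] == g, "cell_id"].tolist()
            counts_g = counts_qc.subset_cells(cells_g)
            sf_spike_g = size_factors(counts_g, feature_scope="spikein")
            fit = fit_technical_cv2(counts_g.spikeins(), sf_spike_g, config.fit_quantile)
            fits[g] = fit
            sf_g = size_factors(counts_g, feature_scope=config.size_factor_scope)
            hvg = hvg_test(
                counts_g.endogenous(), sf_g, fit,
                min_biol_cv2=config.min_biol_cv2, fdr_threshold=config.hvg_fdr,
            )
            _write(hvg, outdir / f"hvg_{g}.tsv")
            hvg_counts[g] = int(hvg["is_hvg"].sum())
            norm_lin = counts_g.endogenous().values / sf_g.to_numpy()[None, :]
            trend = mean_cv2_trend(norm_lin, group=g, floor=1.0)
            pd.DataFrame([{
                "group": g, "slope": trend.slope, "intercept": trend.intercept,
                "n_genes": trend.n_genes, "floor": trend.floor,
            }]).to_csv(outdir / f"noise_trend_{g}.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
        with open(outdir / "technical_fit.json", "w") as fh:
            json.dump({g: asdict(f) for g, f in fits.items()}, fh, indent=2)
        stage_done("variability", n_cells=len(noise), hvg_counts=hvg_counts)
    except Exception as exc:
        raise PipelineError("variability", exc) from exc

    # ---- subgroups ---------------------------------------------------------
    try:
        assignments = []
        correlations = []
        for g in SPLITTABLE_GROUPS:
            if (meta_qc["age_group"] == g).sum() < 2:
                continue
            assign = split_subgroups(meta_qc, g)
            assignments.append(assign)
            correlations.append(genes_detected_generation_cor(meta_qc, g))
            gencor = gene_generation_correlation(
                norm, meta_qc, g, min_cells=config.noise_min_detect_cells
            )
            _write(gencor, outdir / f"generation_correlations_{g}.tsv")
        assignment = pd.concat(assignments, ignore_index=True) if assignments else pd.DataFrame()
        _write(assignment, outdir / "subgroups.tsv")
        _write(pd.DataFrame(correlations), outdir / "genes_detected_correlations.tsv")
        stage_done("subgroups", n_cells_assigned=len(assignment))
    except Exception as exc:
        raise PipelineError("subgroups", exc) from exc

    # ---- regulon -----------------------------------------------------------
    try:
        n_final = {}
        if gene_sets is not None and len(gene_sets) and len(assignment):
            for g in assignment["age_group"].unique():
                comp = compare_regulons(
                    norm, meta_qc, assignment, gene_sets, g,
                    log2fc_threshold=config.regulon_log2fc,
                    welch_p=config.regulon_welch_p,
                    wilcoxon_p=config.regulon_wilcoxon_p,
                    cor_p=config.regulon_cor_p,
                    min_members=config.regulon_min_members,
                )
                _write(comp.table, outdir / f"regulon_comparison_{g}.tsv")
                _write(comp.activity, outdir / f"regulon_cell_activity_{g}.tsv")
                with open(outdir / f"regulon_final_hits_{g}.txt", "w") as fh:
                    fh.write("\n".join(comp.final_hits) + ("\n" if comp.final_hits else ""))
                n_final[g] = len(comp.final_hits)
        stage_done("regulon", n_final_hits=n_final)
    except Exception as exc:
        raise PipelineError("regulon", exc) from exc

    # ---- differential expression -------------------------------------------
    try:
        n_sig = {}
        pairs: list[tuple[str, pd.Series]] = []
        lab_age = meta_qc.set_index("cell_id")["age_group"]
        if {"2h", "36h"} <= set(lab_age.unique()):
            pairs.append(("2h_vs_36h", lab_age[lab_age.isin(["2h", "36h"])]))
        for g in assignment["age_group"].unique() if len(assignment) else []:
            sub = assignment[assignment["age_group"] == g]
            lab = sub.set_index("cell_id")["subgroup"].map(lambda s: f"{g}/{s}")
            if lab.nunique() == 2 and lab.value_counts().min() >= 2:
                pairs.append((f"{g}S_vs_{g}F", lab))
        for name, lab in pairs:
            a, b = sorted(lab.unique())
            res = nb_wald_de(
                counts_qc, sf, lab, group_a=a, group_b=b,
                log2fc_threshold=config.de_log2fc, padj_threshold=config.de_padj,
            )
            _write(res.frame, outdir / f"de_{name.replace('/', '')}.tsv")
            n_sig[name] = int(res.frame["significant"].sum())
        stage_done("de", n_significant=n_sig)
    except Exception as exc:
        raise PipelineError("de", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_pipeline_from_paths(
    config: AnalysisConfig,
    counts_path: str | Path,
    meta_path: str | Path,
    gene_sets_path: str | Path | None,
    outdir: str | Path,
    dialect: str = "tsv",
    seed: int | None = None,
) -> dict:
    counts = read_counts(counts_path, dialect=dialect)
    meta = read_cell_meta(meta_path)
    sets = read_gene_sets(gene_sets_path) if gene_sets_path else None
    return run_pipeline(config, counts, meta, sets, outdir, seed=seed)
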