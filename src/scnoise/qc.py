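"""Cell-level quality control and count normalization.

QC metrics per cell: number of endogenous genes detected (count >= 1),
total mapped reads, and the fraction of reads taken by ERCC spike-ins.
Normalization follows the median-of-ratios size-factor construction with a
log2(pseudocount) transform; TPM is provided for the mean-CV^2 trend plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import CountMatrix, ValidationError


def compute_qc_metrics(counts: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Attach genes_detected, total_mapped_reads and ercc_fraction to meta.

    ``genes_detected`` counts endogenous features (spike-ins excluded) with
    at least one read.  If the metadata lacks total_mapped_reads the column
    sums of the matrix are used.  The ERCC fraction is spike-in reads over
    total mapped reads.
    """
    meta = meta.copy()
    index = {c: i for i, c in enumerate(counts.cell_ids)}
    missing = [c for c in meta["cell_id"] if c not in index]
    if missing:
        raise ValidationError(f"cells in metadata but not in counts: {missing}")
    cols = np.array([index[c] for c in meta["cell_id"]], dtype=int)
    endo = counts.values[~counts.is_spikein][:, cols]
    spike = counts.values[counts.is_spikein][:, cols]
    meta["genes_detected"] = (endo >= 1).sum(axis=0)
    if "total_mapped_reads" not in meta.columns:
        meta["total_mapped_reads"] = endo.sum(axis=0) + spike.sum(axis=0)
    total = meta["total_mapped_reads"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, spike.sum(axis=0) / total, 0.0)
    meta["ercc_fraction"] = frac
    return meta


def qc_filter(
    counts: CountMatrix, meta: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Flag cells passing all three QC thresholds.

    A cell passes iff genes_detected >= min_genes AND total_mapped_reads >=
    min_reads AND ercc_fraction <= max_ercc_fraction; violating any single
    threshold removes the cell.
    """
    config = config or AnalysisConfig()
    meta = compute_qc_metrics(counts, meta)
    meta["qc_pass"] = (
        (meta["genes_detected"] >= config.min_genes)
        & (meta["total_mapped_reads"] >= config.min_reads)
        & (meta["ercc_fraction"] <= config.max_ercc_fraction)
    )
    return meta


def size_factors(
    counts: CountMatrix,
    feature_scope: str = "all",
    poscounts: bool = False,
) -> pd.Series:
    """Median-of-ratios per-cell size factors, rescaled to geometric mean 1.

    For each feature with strictly positive counts in every cell the
    reference is its geometric mean across cells; a cell's factor is the
    median over those features of count / reference.  ``feature_scope``
    selects all features, endogenous genes only, or spike-ins only.  When no
    feature is positive in every cell, the opt-in ``poscounts`` fallback uses
    a positive-part geometric-mean reference.
    """
    if feature_scope == "all":
        sub = counts
    elif feature_scope == "endogenous":
        sub = counts.endogenous()
    elif feature_scope == "spikein":
        sub = counts.spikeins()
    else:
        raise ValueError(f"unknown feature_scope {feature_scope!r}")
    X = sub.values.astype(float)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValidationError("empty matrix in size-factor scope")
    with np.errstate(divide="ignore"):
        logX = np.log(X)
    all_positive = np.isfinite(logX).all(axis=1)
    if all_positive.any() and not poscounts:
        log_ref = logX[all_positive].mean(axis=1)
        log_ratio = logX[all_positive] - log_ref[:, None]
        log_s = np.median(log_ratio, axis=0)
    else:
        if not poscounts:
            raise ValidationError(
                "no feature has positive counts in every cell; "
                "retry with poscounts=True (positive-part geometric-mean reference)"
            )
        # positive-part geometric mean over cells with nonzero counts
        n_pos = np.isfinite(logX).sum(axis=1)
        usable = n_pos > 0
        log_ref = np.where(
            usable, np.where(np.isfinite(logX), logX, 0.0).sum(axis=1) / np.maximum(n_pos, 1), np.nan
        )
        log_s = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            ratios = logX[usable, j] - log_ref[usable]
            ratios = ratios[np.isfinite(ratios)]
            if ratios.size == 0:
                raise ValidationError(f"cell {sub.cell_ids[j]!r} has no usable feature")
            log_s[j] = np.median(ratios)
    log_s = log_s - log_s.mean()  # geometric mean 1 convention
    return pd.Series(np.exp(log_s), index=sub.cell_ids, name="size_factor")


@dataclass
class NormalizedMatrix:
    """log2-normalized expression: log2(count / s_j + pseudocount)."""

    values: np.ndarray
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    is_spikein: np.ndarray
    pseudocount: float

    @property
    def floor(self) -> float:
        """Lowest attainable value, log2(pseudocount); marks zero counts."""
        return float(np.log2(self.pseudocount))

    def detected(self) -> np.ndarray:
        """Boolean mask of entries with nonzero underlying counts."""
        return self.values > self.floor + 1e-12

    def subset_features(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask, dtype=bool)
        return NormalizedMatrix(
            self.values[mask],
            np.asarray(self.feature_ids)[mask],
            self.cell_ids,
            np.asarray(self.is_spikein)[mask],
            self.pseudocount,
        )

    def endogenous(self) -> "NormalizedMatrix":
        return self.subset_features(~np.asarray(self.is_spikein))

    def spikeins(self) -> "NormalizedMatrix":
        return self.subset_features(np.asarray(self.is_spikein))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_ids)


def normalize_log2(
    counts: CountMatrix, sf: pd.Series, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """log2(count / s_j + pseudocount), cells aligned on the size factors."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    missing = [c for c in counts.cell_ids if c not in sf.index]
    if missing:
        raise ValidationError(f"missing size factors for cells: {missing}")
    s = sf.loc[list(counts.cell_ids)].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValidationError("size factors must be positive")
    values = np.log2(counts.values / s[None, :] + pseudocount)
    return NormalizedMatrix(
        values, counts.feature_ids, counts.cell_ids, counts.is_spikein, pseudocount
    )


def tpm(counts: CountMatrix, lengths: pd.Series | np.ndarray) -> pd.DataFrame:
    """Transcripts per kilobase per million mapped reads, per cell.

    Cells with no counts at all yield an all-zero column rather than NaN.
    """
    if isinstance(lengths, pd.Series):
        missing = [f for f in counts.feature_ids if f not in lengths.index]
        if missing:
            raise ValidationError(f"missing lengths for features: {missing}")
        L = lengths.loc[list(counts.feature_ids)].to_numpy(dtype=float)
    else:
        L = np.asarray(lengths, dtype=float)
        if L.shape[0] != counts.n_features:
            raise ValidationError("length vector does not match feature count")
    if (L <= 0).any():
        raise ValidationError("feature lengths must be positive")
    rate = counts.values / (L[:, None] / 1000.0)
    total = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, rate / total[None, :] * 1e6, 0.0)
    return pd.DataFrame(out, index=counts.feature_ids, columns=counts.cell_ids)
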