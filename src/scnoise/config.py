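"""Analysis configuration: every stage threshold in one auditable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and knobs for the full pipeline.

    The defaults are the study conditions: QC removal below 1000 detected
    genes or 40,000 mapped reads or above an ERCC read fraction of 0.74;
    highly-variable-gene calls at biological CV^2 > 0.25 and FDR < 0.1;
    regulon screening at log2FC > 1 with Welch p < 0.01, per-cell Wilcoxon
    p < 1e-4 and generation-correlation p < 0.05; differential expression at
    |log2FC| > 1 and BH-adjusted p < 0.05.
    """

    # QC
    min_genes: int = 1000
    min_reads: int = 40000
    max_ercc_fraction: float = 0.74
    # normalization
    pseudocount: float = 1.0
    size_factor_scope: str = "all"  # all | endogenous | spikein
    # HVG detection
    min_biol_cv2: float = 0.25
    hvg_fdr: float = 0.1
    fit_quantile: float = 0.4
    # per-cell noise
    noise_min_detect_cells: int = 5
    t_tolerance: float = 1e-6
    # regulon procedure
    regulon_log2fc: float = 1.0
    regulon_welch_p: float = 0.01
    regulon_wilcoxon_p: float = 1e-4
    regulon_cor_p: float = 0.05
    regulon_min_members: int = 5
    # differential expression
    de_log2fc: float = 1.0
    de_padj: float = 0.05
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_genes",
            "min_reads",
            "pseudocount",
            "min_biol_cv2",
            "regulon_log2fc",
            "de_log2fc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "max_ercc_fraction",
            "hvg_fdr",
            "fit_quantile",
            "regulon_welch_p",
            "regulon_wilcoxon_p",
            "regulon_cor_p",
            "de_padj",
        ):
            value = getattr(self, name)
            if not (0 < value < 1):
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        if self.size_factor_scope not in {"all", "endogenous", "spikein"}:
            raise ValueError(f"unknown size_factor_scope {self.size_factor_scope!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
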