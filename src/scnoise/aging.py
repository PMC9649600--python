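"""Slow/fast-divider subgroups and generation-correlation analyses.

Cells of the 16h and 36h age groups are split at their group's mean
generation: generation >= mean is fast-dividing (F), below is slow-dividing
(S).  Gene expression and per-cell summaries are then correlated against
generation (Pearson, exact t transform with n - 2 df for the p-value).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

SPLITTABLE_GROUPS = ("16h", "36h")


def split_subgroups(meta: pd.DataFrame, group: str) -> pd.DataFrame:
    """Assign S/F subgroup labels within one age group.

    Uses QC-passing cells only (when a qc_pass column is present).  The
    threshold is the arithmetic mean generation; ties at the mean go to F.
    All-equal generations make the split degenerate and raise.
    """
    if group not in SPLITTABLE_GROUPS:
        raise ValueError(f"subgroups are defined for {SPLITTABLE_GROUPS}, not {group!r}")
    cells = meta[meta["age_group"] == group]
    if "qc_pass" in cells.columns:
        cells = cells[cells["qc_pass"]]
    if len(cells) < 2:
        raise ValidationError(f"fewer than 2 usable cells in group {group!r}")
    gen = cells["generation"].to_numpy(dtype=float)
    threshold = float(gen.mean())
    if np.allclose(gen, gen[0]):
        raise ValidationError(f"degenerate split: all generations equal in {group!r}")
    out = cells[["cell_id", "age_group", "generation"]].copy()
    out["subgroup"] = np.where(gen >= threshold, "F", "S")
    out["group_mean_generation"] = threshold
    return out.reset_index(drop=True)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def genes_detected_generation_cor(meta: pd.DataFrame, group: str) -> dict:
    """Pearson correlation of genes detected vs generation within a group."""
    cells = meta[meta["age_group"] == group]
    if "qc_pass" in cells.columns:
        cells = cells[cells["qc_pass"]]
    if len(cells) < 3:
        raise ValidationError(f"fewer than 3 cells in group {group!r}")
    r, p = _pearson_with_p(
        cells["genes_detected"].to_numpy(dtype=float),
        cells["generation"].to_numpy(dtype=float),
    )
    return {"target": "genes_detected", "group": group, "R": r, "p": p, "n": len(cells)}


def gene_generation_correlation(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    group: str,
    genes: list[str] | None = None,
    min_cells: int = 5,
    method: str = "pearson",
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene correlation of log2-normalized expression with generation.

    Genes detected in fewer than ``min_cells`` cells of the group are
    skipped; constant-expression genes are skipped and logged.  With
    ``adjust`` a BH column over the tested genes is added.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    meta_idx = meta.set_index("cell_id")
    in_group = [
        c for c in norm.cell_ids if meta_idx.loc[c, "age_group"] == group
    ]
    if len(in_group) < 3:
        raise ValidationError(f"fewer than 3 cells in group {group!r}")
    sub = norm.endogenous()
    col = {c: i for i, c in enumerate(sub.cell_ids)}
    cols = np.array([col[c] for c in in_group])
    X = sub.values[:, cols]
    gen = meta_idx.loc[in_group, "generation"].to_numpy(dtype=float)
    ids = np.asarray(sub.feature_ids, dtype=object)

    keep = (X > sub.floor + 1e-12).sum(axis=1) >= min_cells
    if genes is not None:
        keep &= np.isin(ids.astype(str), list(genes))
    constant = X.std(axis=1) == 0
    n_const = int((keep & constant).sum())
    if n_const:
        logger.info("%d constant-expression genes skipped", n_const)
    keep &= ~constant
    if not keep.any():
        raise ValidationError("no genes eligible for correlation")

    if method == "spearman":
        Xk = stats.rankdata(X[keep], axis=1)
        g = stats.rankdata(gen)
    else:
        Xk, g = X[keep], gen
    n = len(g)
    Xc = Xk - Xk.mean(axis=1, keepdims=True)
    gc = g - g.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (gc**2).sum())
    r = np.clip((Xc @ gc) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r * r, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame({"gene": ids[keep], "group": group, "R": r, "p": p, "n": n})
    if adjust:
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
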