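"""Differential TF-regulon activity between slow/fast age subgroups.

Three stringent screens are intersected per transcription factor:

1. Median target expression per cell, compared between subgroups: pass if
   log2FC (F minus S, in log2 space) exceeds 1 and a Welch t-test gives
   p < 0.01.
2. Per-cell regulon activity: a one-sided Wilcoxon rank-sum test of the
   TF's detected targets against all other genes detected in that cell;
   activity is "on" at p < 1e-4 and a TF passes when the fraction of "on"
   cells is strictly greater in F than in S (optionally a one-sided Fisher
   exact test on on/off counts).
3. Correlation of the per-cell target summary with generation within the
   age group: pass at p < 0.05 with a positive coefficient.

The final hit list is the intersection of the three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .qc import NormalizedMatrix
from .aging import _pearson_with_p

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-cell rank-sum machinery
# ---------------------------------------------------------------------------


def ranksum_pvalue_greater(
    values: np.ndarray, target_mask: np.ndarray, exact_limit: int = 20000
) -> tuple[float, float]:
    """One-sided ('targets higher') Wilcoxon rank-sum p for one cell.

    Returns (W, p) where W is the sum of the targets' midranks among
    ``values``.  When the number of rank subsets C(n, k) is at most
    ``exact_limit`` the null is enumerated exactly (valid with ties);
    otherwise a normal approximation with tie correction and continuity
    correction is used.
    """
    values = np.asarray(values, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    n = len(values)
    k = int(target_mask.sum())
    if k < 1 or k >= n:
        raise ValidationError("targets must be a proper non-empty subset")
    ranks = stats.rankdata(values)
    W = float(ranks[target_mask].sum())
    if comb(n, k) <= exact_limit:
        count = 0
        total = 0
        for subset in combinations(range(n), k):
            total += 1
            if ranks[list(subset)].sum() >= W - 1e-9:
                count += 1
        return W, count / total
    # normal approximation with tie correction
    mean = k * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = k * (n - k) / (12.0 * n * (n - 1)) * (n**3 - n - tie_term)
    if var <= 0:
        return W, 1.0
    z = (W - mean - 0.5) / np.sqrt(var)
    return W, float(stats.norm.sf(z))


def per_cell_regulon_activity(
    norm: NormalizedMatrix,
    sets: GeneSetCollection,
    wilcoxon_p: float = 1e-4,
    min_targets: int = 3,
    exact_limit: int = 20000,
) -> pd.DataFrame:
    """Per-cell, per-TF regulon activity calls.

    Only genes with a nonzero count in the cell enter the test; a TF needs
    at least ``min_targets`` detected targets in the cell, else its activity
    is undefined (NaN p) for that cell.
    """
    endo = norm.endogenous()
    ids = np.asarray(endo.feature_ids, dtype=object).astype(str)
    detected = endo.detected()
    target_masks = {
        tf: np.isin(ids, list(members)) for tf, members in sets.items()
    }
    rows = []
    for j, cell in enumerate(endo.cell_ids):
        det = detected[:, j]
        n_det = int(det.sum())
        if n_det == 0:
            continue
        vals = endo.values[det, j]
        ranks = stats.rankdata(vals)
        # tie statistics shared by every TF tested in this cell
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum())
        for tf, mask in target_masks.items():
            tmask = mask[det]
            k = int(tmask.sum())
            if k < min_targets or k >= n_det:
                rows.append((tf, cell, n_det, k, np.nan, np.nan, None))
                continue
            W = float(ranks[tmask].sum())
            if comb(n_det, k) <= exact_limit:
                _, p = ranksum_pvalue_greater(vals, tmask, exact_limit=exact_limit)
            else:
                mean = k * (n_det + 1) / 2.0
                var = (
                    k
                    * (n_det - k)
                    / (12.0 * n_det * (n_det - 1))
                    * (n_det**3 - n_det - tie_term)
                )
                p = 1.0 if var <= 0 else float(
                    stats.norm.sf((W - mean - 0.5) / np.sqrt(var))
                )
            rows.append((tf, cell, n_det, k, W, p, bool(p < wilcoxon_p)))
    return pd.DataFrame(
        rows, columns=["tf", "cell_id", "n_detected", "n_targets", "W", "p", "active"]
    )


# ---------------------------------------------------------------------------
# subgroup-level approaches
# ---------------------------------------------------------------------------


def _target_summaries(
    norm: NormalizedMatrix,
    sets: GeneSetCollection,
    cells: list[str],
    summary: str = "median",
    min_members: int = 5,
) -> pd.DataFrame:
    """Per-cell summary (median/mean) of log2-normalized target expression."""
    endo = norm.endogenous()
    ids = np.asarray(endo.feature_ids, dtype=object).astype(str)
    col = {c: i for i, c in enumerate(endo.cell_ids)}
    cols = np.array([col[c] for c in cells])
    agg = np.median if summary == "median" else np.mean
    data = {}
    for tf, members in sets.items():
        mask = np.isin(ids, list(members))
        if mask.sum() < min_members:
            logger.info("TF %s: %d mapped members < %d, skipped", tf, mask.sum(), min_members)
            continue
        data[tf] = agg(endo.values[mask][:, cols], axis=0)
    return pd.DataFrame(data, index=cells)


def approach1_median_shift(
    norm: NormalizedMatrix,
    assignment: pd.DataFrame,
    sets: GeneSetCollection,
    log2fc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    summary: str = "median",
    min_members: int = 5,
) -> pd.DataFrame:
    """Approach 1: subgroup shift of per-cell median target expression.

    log2FC is the difference of subgroup means of the per-cell summaries
    (already in log2 space); the test is Welch's two-sample t.  A TF passes
    when log2FC > threshold in the F direction and p < p_threshold.
    """
    s_cells = assignment.loc[assignment["subgroup"] == "S", "cell_id"].tolist()
    f_cells = assignment.loc[assignment["subgroup"] == "F", "cell_id"].tolist()
    if len(s_cells) < 2 or len(f_cells) < 2:
        raise ValidationError("each subgroup needs at least 2 cells")
    summaries = _target_summaries(norm, sets, s_cells + f_cells, summary, min_members)
    rows = []
    for tf in summaries.columns:
        s_vals = summaries.loc[s_cells, tf].to_numpy()
        f_vals = summaries.loc[f_cells, tf].to_numpy()
        log2fc = float(f_vals.mean() - s_vals.mean())
        if np.var(s_vals) == 0 and np.var(f_vals) == 0:
            p = 1.0 if np.isclose(log2fc, 0) else 0.0
        else:
            p = float(stats.ttest_ind(f_vals, s_vals, equal_var=False).pvalue)
        rows.append(
            {
                "tf": tf,
                "log2fc": log2fc,
                "welch_p": p,
                "passed": bool(log2fc > log2fc_threshold and p < p_threshold),
            }
        )
    return pd.DataFrame(rows)


def approach2_percell_activity(
    norm: NormalizedMatrix,
    assignment: pd.DataFrame,
    sets: GeneSetCollection,
    wilcoxon_p: float = 1e-4,
    min_targets: int = 3,
    rule: str = "fraction",
    fisher_p: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Approach 2: per-cell on/off activity aggregated by subgroup.

    Default ``rule='fraction'``: pass when the fraction of "on" cells
    (among cells with defined activity) is strictly greater in F than in S.
    ``rule='fisher'`` additionally requires a one-sided Fisher exact test on
    the on/off counts at ``fisher_p``.
    """
    cells = assignment["cell_id"].tolist()
    sub_norm = NormalizedMatrix(
        norm.values[:, [list(norm.cell_ids).index(c) for c in cells]],
        norm.feature_ids,
        np.asarray(cells, dtype=object),
        norm.is_spikein,
        norm.pseudocount,
    )
    activity = per_cell_regulon_activity(
        sub_norm, sets, wilcoxon_p=wilcoxon_p, min_targets=min_targets
    )
    label = assignment.set_index("cell_id")["subgroup"]
    activity = activity.assign(subgroup=activity["cell_id"].map(label))
    rows = []
    for tf, grp in activity.groupby("tf", sort=False):
        defined = grp.dropna(subset=["p"])
        on = {}
        frac = {}
        n_def = {}
        for sg in ("S", "F"):
            sub = defined[defined["subgroup"] == sg]
            n_def[sg] = len(sub)
            on[sg] = int(sub["active"].sum()) if len(sub) else 0
            frac[sg] = on[sg] / n_def[sg] if n_def[sg] else np.nan
        passed = bool(
            n_def["S"] > 0 and n_def["F"] > 0 and frac["F"] > frac["S"]
        )
        if rule == "fisher" and passed:
            table = [
                [on["F"], n_def["F"] - on["F"]],
                [on["S"], n_def["S"] - on["S"]],
            ]
            p_fisher = stats.fisher_exact(table, alternative="greater")[1]
            passed = bool(p_fisher < fisher_p)
        rows.append(
            {
                "tf": tf,
                "frac_on_S": frac["S"],
                "frac_on_F": frac["F"],
                "n_cells_S": n_def["S"],
                "n_cells_F": n_def["F"],
                "passed": passed,
            }
        )
    return activity, pd.DataFrame(rows)


def approach3_generation_cor(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    sets: GeneSetCollection,
    group: str,
    cor_p: float = 0.05,
    summary: str = "median",
    min_members: int = 5,
) -> pd.DataFrame:
    """Approach 3: per-cell target summary correlated with generation.

    Pass for F-activated candidates: p < cor_p AND R > 0 (fast dividers
    have higher generation, so F-activation implies a positive slope).
    """
    meta_idx = meta.set_index("cell_id")
    cells = [c for c in norm.cell_ids if meta_idx.loc[c, "age_group"] == group]
    if len(cells) < 3:
        raise ValidationError(f"fewer than 3 cells in group {group!r}")
    gen = meta_idx.loc[cells, "generation"].to_numpy(dtype=float)
    summaries = _target_summaries(norm, sets, cells, summary, min_members)
    rows = []
    for tf in summaries.columns:
        r, p = _pearson_with_p(summaries[tf].to_numpy(), gen)
        rows.append(
            {
                "tf": tf,
                "R": r,
                "cor_p": p,
                "passed": bool(np.isfinite(r) and p < cor_p and r > 0),
            }
        )
    return pd.DataFrame(rows)


def intersect_hits(*hit_lists: list[str]) -> list[str]:
    """Order-stable intersection (order of the first list)."""
    if not hit_lists:
        return []
    common = set(hit_lists[0])
    for other in hit_lists[1:]:
        common &= set(other)
    return [tf for tf in hit_lists[0] if tf in common]


# ---------------------------------------------------------------------------
# combined procedure
# ---------------------------------------------------------------------------


@dataclass
class RegulonComparison:
    """Outcome of the three-approach screen for one subgroup pair."""

    group: str
    table: pd.DataFrame
    activity: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def final_hits(self) -> list[str]:
        return self.table.loc[self.table["final_hit"], "tf"].tolist()

    def summary(self) -> str:
        lines = [
            f"Regulon screen, {group_label(self.group)}:",
            f"  TFs tested        : {len(self.table)}",
            f"  approach 1 hits   : {int(self.table['a1_passed'].sum())}",
            f"  approach 1 & 2    : {int((self.table['a1_passed'] & self.table['a2_passed']).sum())}",
            f"  final (1 & 2 & 3) : {len(self.final_hits)}"
            + (f" -> {', '.join(self.final_hits)}" if self.final_hits else ""),
        ]
        return "\n".join(lines)


def group_label(group: str) -> str:
    return f"{group}/S vs {group}/F"


def compare_regulons(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    assignment: pd.DataFrame,
    sets: GeneSetCollection,
    group: str,
    log2fc_threshold: float = 1.0,
    welch_p: float = 0.01,
    wilcoxon_p: float = 1e-4,
    cor_p: float = 0.05,
    min_members: int = 5,
    summary: str = "median",
    rule: str = "fraction",
) -> RegulonComparison:
    """Run all three approaches for one age group's S/F pair and intersect."""
    sub_assign = assignment[assignment["age_group"] == group]
    a1 = approach1_median_shift(
        norm, sub_assign, sets, log2fc_threshold, welch_p, summary, min_members
    )
    activity, a2 = approach2_percell_activity(
        norm, sub_assign, sets, wilcoxon_p=wilcoxon_p, rule=rule
    )
    a3 = approach3_generation_cor(
        norm, meta, sets, group, cor_p=cor_p, summary=summary, min_members=min_members
    )
    table = (
        a1.rename(columns={"passed": "a1_passed"})
        .merge(a2.rename(columns={"passed": "a2_passed"}), on="tf", how="left")
        .merge(a3.rename(columns={"passed": "a3_passed"}), on="tf", how="left")
    )
    for c in ("a2_passed", "a3_passed"):
        table[c] = table[c].fillna(False).astype(bool)
    hits = intersect_hits(
        table.loc[table["a1_passed"], "tf"].tolist(),
        table.loc[table["a2_passed"], "tf"].tolist(),
        table.loc[table["a3_passed"], "tf"].tolist(),
    )
    table["final_hit"] = table["tf"].isin(hits)
    return RegulonComparison(group=group, table=table, activity=activity)
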