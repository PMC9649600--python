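"""Cell-to-cell transcriptional variability estimators.

Two complementary estimators are implemented:

1. A per-cell noise ratio.  For cell j in age group i, biological variation
   is ``b = 1 - cor(x_ij, u_i)`` where ``x_ij`` is the cell's endogenous
   log2-normalized expression vector and ``u_i`` the mean vector of its age
   group; technical variation is ``t = 1 - cor(x_contr, u_contr)`` computed
   the same way on the ERCC spike-ins with the mean taken over all cells.
   The ratio b/t expresses biological noise in units of technical noise and
   is compared between age groups with a Wilcoxon rank-sum test.

2. A highly-variable-gene (HVG) test.  The spike-ins calibrate a technical
   variance model CV^2 = a1/mu + alpha0 (gamma-family GLM, identity link);
   each endogenous gene's observed CV^2 is then tested against the null that
   its biological CV^2 does not exceed omega via a scaled chi-square with
   m - 1 degrees of freedom, followed by Benjamini-Hochberg correction.
   HVGs must satisfy biological CV^2 > omega AND FDR below threshold.

A log-log ordinary-least-squares fit of CV^2 on mean expression summarizes
the per-group noise trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ValidationError
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-cell noise ratio
# ---------------------------------------------------------------------------


def _pearson_to_mean(X: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of X's columns with vector u."""
    Xc = X - X.mean(axis=0, keepdims=True)
    uc = u - u.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (uc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * uc[:, None]).sum(axis=0) / denom
    return r


def cell_noise_ratio(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    min_detect_cells: int = 5,
    method: str = "pearson",
    t_tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Per-cell biological (b), technical (t) variation and their ratio.

    Cells are the QC-passing cells present in ``norm``; ``meta`` supplies
    their age groups.  Endogenous genes detected in fewer than
    ``min_detect_cells`` cells are dropped before computing b (correlations
    over near-empty genes are unstable).  Cells with t below ``t_tolerance``
    get an undefined (NaN) ratio and are logged.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    meta = meta.set_index("cell_id").loc[list(norm.cell_ids)]
    groups = meta["age_group"].to_numpy()

    endo = norm.endogenous()
    keep = endo.detected().sum(axis=1) >= min_detect_cells
    E = endo.values[keep]
    S = norm.spikeins().values
    if S.shape[0] < 2:
        raise ValidationError("need at least 2 spike-in features for t")
    if method == "spearman":
        E = stats.rankdata(E, axis=0)
        S = stats.rankdata(S, axis=0)

    b = np.full(len(norm.cell_ids), np.nan)
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValidationError(f"age group {g!r} has fewer than 2 cells")
        u = E[:, mask].mean(axis=1)
        b[mask] = 1.0 - _pearson_to_mean(E[:, mask], u)
    u_contr = S.mean(axis=1)  # global spike-in mean, all cells
    t = 1.0 - _pearson_to_mean(S, u_contr)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(t) > t_tolerance, b / t, np.nan)
    n_undef = int(np.isnan(ratio).sum())
    if n_undef:
        logger.info("%d cells with technical variation below tolerance", n_undef)
    return pd.DataFrame(
        {
            "cell_id": norm.cell_ids,
            "age_group": groups,
            "b": b,
            "t": t,
            "ratio": ratio,
        }
    )


def compare_group_noise(
    estimates: pd.DataFrame,
    group_a: str,
    group_b: str,
    value: str = "ratio",
) -> dict:
    """Two-sided Wilcoxon rank-sum test on per-cell noise between two groups."""
    a = estimates.loc[estimates["age_group"] == group_a, value].dropna().to_numpy()
    b = estimates.loc[estimates["age_group"] == group_b, value].dropna().to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need at least 3 cells with defined values per group")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        warnings.warn("all values tied; p set to 1", stacklevel=2)
        return {
            "group_a": group_a,
            "group_b": group_b,
            "W": len(a) * len(b) / 2.0,
            "p": 1.0,
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "n_a": len(a),
            "n_b": len(b),
        }
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "group_a": group_a,
        "group_b": group_b,
        "W": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": len(a),
        "n_b": len(b),
    }


# ---------------------------------------------------------------------------
# spike-in technical variance model (CV^2 ~ a1/mu + alpha0)
# ---------------------------------------------------------------------------


@dataclass
class TechnicalFit:
    """Fitted technical-noise parameters.

    a1 is the slope of CV^2 against 1/mean (units of mean normalized
    expression); alpha0 the asymptotic CV^2 floor (unitless, clipped at 0).
    """

    a1: float
    alpha0: float
    fit_domain: float
    n_spikeins_fit: int
    method: str = "glm-gamma"

    def cv2_tech(self, mu: np.ndarray | float) -> np.ndarray | float:
        return self.a1 / mu + self.alpha0

    def summary(self) -> str:
        return (
            "Technical variance fit: CV^2 = a1/mu + alpha0\n"
            f"  a1        = {self.a1:.6g}\n"
            f"  alpha0    = {self.alpha0:.6g}\n"
            f"  fit floor = {self.fit_domain:.6g} (mean normalized expression)\n"
            f"  spike-ins = {self.n_spikeins_fit}\n"
            f"  method    = {self.method}"
        )


def _normalized_mean_cv2(values: np.ndarray, s: np.ndarray):
    norm = values / s[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    return mu, cv2


class SpikeInNoiseModel:
    """Technical CV^2-vs-mean model estimated from ERCC spike-in counts.

    Parameters
    ----------
    spike_counts
        CountMatrix restricted to (or containing) spike-in features; only
        spike-in rows are used.
    size_factors
        Per-cell scaling divisors covering every cell of the matrix
        (typically computed with spike-in scope).
    fit_quantile
        Spike-ins with mean below this quantile of the positive spike-in
        means are excluded from the regression; low-copy species destabilize
        the gamma GLM.
    """

    def __init__(
        self,
        spike_counts: CountMatrix,
        size_factors: pd.Series,
        fit_quantile: float = 0.4,
    ) -> None:
        sub = spike_counts.spikeins() if (~spike_counts.is_spikein).any() else spike_counts
        if sub.n_features < 2:
            raise ValidationError("need at least 2 spike-in species")
        self.counts = sub
        missing = [c for c in sub.cell_ids if c not in size_factors.index]
        if missing:
            raise ValidationError(f"missing size factors for cells: {missing}")
        self.size_factors = size_factors.loc[list(sub.cell_ids)]
        self.fit_quantile = fit_quantile

    def fit(self) -> TechnicalFit:
        mu, cv2 = _normalized_mean_cv2(
            self.counts.values.astype(float), self.size_factors.to_numpy(dtype=float)
        )
        ok = (mu > 0) & np.isfinite(cv2)
        floor = float(np.quantile(mu[ok], self.fit_quantile)) if ok.any() else 0.0
        use = ok & (mu >= floor)
        if use.sum() < 2:
            raise ValidationError(
                f"only {int(use.sum())} spike-in species above the fit floor; need >= 2"
            )
        exog = np.column_stack([1.0 / mu[use], np.ones(int(use.sum()))])
        method = "glm-gamma"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(
                    cv2[use],
                    exog,
                    family=sm.families.Gamma(link=sm.families.links.Identity()),
                )
                res = glm.fit(maxiter=200)
            a1, alpha0 = res.params
            if not (np.isfinite(a1) and np.isfinite(alpha0)) or a1 <= 0:
                raise RuntimeError("gamma GLM produced unusable parameters")
        except Exception:
            logger.warning("gamma GLM failed; falling back to OLS of CV^2 on 1/mu")
            coef, *_ = np.linalg.lstsq(exog, cv2[use], rcond=None)
            a1, alpha0 = coef
            method = "ols-fallback"
        return TechnicalFit(
            a1=float(a1),
            alpha0=float(max(alpha0, 0.0)),
            fit_domain=floor,
            n_spikeins_fit=int(use.sum()),
            method=method,
        )


def fit_technical_cv2(
    spike_counts: CountMatrix,
    sf_spikein: pd.Series,
    fit_quantile: float = 0.4,
) -> TechnicalFit:
    """Functional wrapper around :class:`SpikeInNoiseModel`."""
    return SpikeInNoiseModel(spike_counts, sf_spikein, fit_quantile).fit()


# ---------------------------------------------------------------------------
# HVG test
# ---------------------------------------------------------------------------


def hvg_test(
    endog_counts: CountMatrix,
    sf: pd.Series,
    fit: TechnicalFit,
    min_biol_cv2: float = 0.25,
    fdr_threshold: float = 0.1,
    psi: float = 1.0,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene HVG test against the spike-in technical expectation.

    For a gene with normalized mean mu and observed cv2 among m cells the
    null CV^2 is ``a1 * psi / mu + alpha0 + omega * (1 + alpha0)`` with
    omega = ``min_biol_cv2``; the statistic ``(m - 1) * cv2 / cv2_null`` is
    referred to the upper tail of chi-square with m - 1 df, BH-corrected.
    ``psi`` is the spike-in/endogenous size-factor cross-term (1 when one
    size-factor set normalizes both).  Genes with zero mean are excluded.
    ``exclude`` drops listed gene ids (e.g. cell-cycle periodic genes)
    before testing.
    """
    sub = endog_counts.endogenous() if endog_counts.is_spikein.any() else endog_counts
    if exclude:
        sub = sub.subset_features(~np.isin(sub.feature_ids.astype(str), list(exclude)))
    m = sub.n_cells
    if m < 3:
        raise ValidationError("need at least 3 cells for the HVG test")
    s = sf.loc[list(sub.cell_ids)].to_numpy(dtype=float)
    mu, cv2 = _normalized_mean_cv2(sub.values.astype(float), s)
    keep = mu > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%d genes with zero mean excluded from HVG test", n_dropped)
    mu_k, cv2_k = mu[keep], cv2[keep]
    omega = min_biol_cv2
    cv2_tech = fit.a1 / mu_k + fit.alpha0
    cv2_biol = cv2_k - cv2_tech
    cv2_null = fit.a1 * psi / mu_k + fit.alpha0 + omega * (1.0 + fit.alpha0)
    chi2_stat = (m - 1) * cv2_k / cv2_null
    p = stats.chi2.sf(chi2_stat, df=m - 1)
    fdr = multipletests(p, method="fdr_bh")[1]
    is_hvg = (cv2_biol > omega) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {
            "gene": sub.feature_ids[keep],
            "mean": mu_k,
            "cv2": cv2_k,
            "cv2_tech": cv2_tech,
            "cv2_biol": cv2_biol,
            "chi2_stat": chi2_stat,
            "p": p,
            "fdr": fdr,
            "is_hvg": is_hvg,
            "m": m,
        }
    )


# ---------------------------------------------------------------------------
# mean-CV^2 noise trend
# ---------------------------------------------------------------------------


@dataclass
class NoiseTrendFit:
    """OLS fit of log10(CV^2) on log10(mean expression) for one group."""

    group: str
    slope: float
    intercept: float
    n_genes: int
    floor: float
    cv2_at_ref: dict[float, float] = field(default_factory=dict)

    def predict_cv2(self, mean: float) -> float:
        return float(10 ** (self.intercept + self.slope * np.log10(mean)))

    def summary(self) -> str:
        refs = ", ".join(f"CV^2({m:g}) = {v:.4g}" for m, v in self.cv2_at_ref.items())
        return (
            f"Noise trend [{self.group}]: log10(CV^2) = "
            f"{self.intercept:.4f} + {self.slope:.4f} * log10(mean); "
            f"n = {self.n_genes}, floor = {self.floor:g}"
            + (f"; {refs}" if refs else "")
        )


def mean_cv2_trend(
    expr,
    group: str = "",
    floor: float = 1.0,
    ref_levels: tuple[float, ...] = (100.0, 1000.0),
) -> NoiseTrendFit:
    """Fit the per-group noise trend on a linear-scale expression matrix.

    ``expr`` is a genes x cells DataFrame or array of TPM or normalized
    counts (not log-transformed).  Genes with mean below ``floor`` or zero
    variance are excluded; at least 10 genes must remain.
    """
    X = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, dtype=float)
    mu = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    keep = (mu > floor) & (var > 0)
    if keep.sum() < 10:
        raise ValidationError(
            f"only {int(keep.sum())} genes above floor {floor:g}; need >= 10"
        )
    cv2 = var[keep] / mu[keep] ** 2
    x = np.log10(mu[keep])
    y = np.log10(cv2)
    slope, intercept = np.polyfit(x, y, deg=1)
    if not np.isfinite(slope):
        raise ValidationError("noise-trend slope is not finite")
    fit = NoiseTrendFit(
        group=group,
        slope=float(slope),
        intercept=float(intercept),
        n_genes=int(keep.sum()),
        floor=floor,
    )
    fit.cv2_at_ref = {float(r): fit.predict_cv2(r) for r in ref_levels}
    return fit
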