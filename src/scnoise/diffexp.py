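"""Negative-binomial Wald differential expression between two cell groups.

Per gene a negative-binomial GLM with a two-level group factor and log
size-factor offsets is fitted.  Gene-wise dispersions are estimated by
maximum likelihood (method-of-moments fallback), shrunk toward a parametric
mean-dispersion trend ``alpha(mu) = a/mu + b`` by an empirical-Bayes step in
log space, and the group coefficient is tested with a Wald z statistic.
P-values are BH-adjusted across genes with nonzero counts.  This estimator
follows the standard shrinkage recipe for small-sample count DE but does not
promise numerical identity with any particular external tool; see the
optional R bridge for exact DESeq2 runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_MIN_ALPHA = 1e-8
_MAX_ALPHA = 10.0


def _nb_negloglik(log_alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    alpha = np.exp(log_alpha)
    r = 1.0 / alpha
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return -float(ll.sum())


def _dispersion_mle(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Gene-wise dispersion: MLE given fitted means, MoM fallback/start."""
    resid = ((y - mu) ** 2 - mu) / mu**2
    mom = max(float(resid.sum()) / max(len(y) - n_params, 1), _MIN_ALPHA)
    try:
        res = optimize.minimize_scalar(
            _nb_negloglik,
            bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
            args=(y, mu),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if res.success and np.isfinite(res.fun):
            return float(np.exp(res.x))
    except Exception:  # pragma: no cover - optimizer edge cases
        pass
    return min(max(mom, _MIN_ALPHA), _MAX_ALPHA)


def _fit_dispersion_trend(base_mean: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Parametric trend alpha = a / mean + b on informative genes."""
    use = (alpha > 1e-6) & (alpha < _MAX_ALPHA * 0.99) & (base_mean > 0)
    if use.sum() < 10:
        med = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01
        return 0.0, max(med, _MIN_ALPHA)
    exog = np.column_stack([1.0 / base_mean[use], np.ones(int(use.sum()))])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                alpha[use],
                exog,
                family=sm.families.Gamma(link=sm.families.links.Identity()),
            ).fit(maxiter=100)
        a, b = res.params
        if not np.all(np.isfinite([a, b])):
            raise RuntimeError
    except Exception:
        coef, *_ = np.linalg.lstsq(exog, alpha[use], rcond=None)
        a, b = coef
    return max(float(a), 0.0), max(float(b), _MIN_ALPHA)


_SE_LOG_CAP = 4.0  # ln-scale Wald SE beyond which the fit is degenerate


def _moderated_wald(
    y: np.ndarray, sf: np.ndarray, is_b: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Continuity-corrected group-mean Wald estimate for separated genes.

    When one group has no counts the GLM group coefficient diverges and its
    Wald SE explodes; a 0.5-count correction on the group totals with a
    delta-method variance keeps the test informative.
    """
    est = []
    var = []
    for mask in (~is_b, is_b):
        total = y[mask].sum() + 0.5
        depth = sf[mask].sum()
        mu = total / depth
        # Var(sum y) for NB counts with per-cell means mu * s_j
        v_sum = float((mu * sf[mask] + alpha * (mu * sf[mask]) ** 2).sum()) + 0.25
        est.append(np.log(mu))
        var.append(v_sum / total**2)
    lfc = est[1] - est[0]
    se = float(np.sqrt(var[0] + var[1]))
    return lfc, se


@dataclass
class DEResults:
    """Per-gene Wald-test table with the fixed significance rule applied."""

    frame: pd.DataFrame
    group_a: str
    group_b: str
    log2fc_threshold: float
    padj_threshold: float

    def filter_significant(
        self, log2fc: float | None = None, padj: float | None = None
    ) -> pd.DataFrame:
        return filter_significant(
            self.frame,
            log2fc if log2fc is not None else self.log2fc_threshold,
            padj if padj is not None else self.padj_threshold,
        )

    def summary(self) -> str:
        sig = self.filter_significant()
        up = int((sig["direction"] == "up").sum())
        down = int((sig["direction"] == "down").sum())
        return (
            f"NB Wald DE: {self.group_b} vs {self.group_a}\n"
            f"  genes tested : {len(self.frame)}\n"
            f"  significant  : {len(sig)} (|log2FC| > {self.log2fc_threshold:g}, "
            f"padj < {self.padj_threshold:g})\n"
            f"  up in {self.group_b}   : {up}\n"
            f"  down in {self.group_b} : {down}"
        )


class NegativeBinomialDE:
    """Two-group NB Wald differential expression model.

    Parameters
    ----------
    counts
        Raw counts (endogenous features are used; spike-ins dropped).
    size_factors
        Per-cell divisors entering as log offsets.
    labels
        Mapping or Series cell_id -> group with exactly two levels.
    group_a, group_b
        Reference and comparison level; log2FC is B over A.
    """

    def __init__(
        self,
        counts: CountMatrix,
        size_factors: pd.Series,
        labels: pd.Series,
        group_a: str | None = None,
        group_b: str | None = None,
        prior_var: float = 0.25,
    ) -> None:
        sub = counts.endogenous() if counts.is_spikein.any() else counts
        labels = pd.Series(labels)
        cells = [c for c in sub.cell_ids if c in labels.index]
        if len(cells) < sub.n_cells:
            sub = sub.subset_cells(cells)
        lab = labels.loc[list(sub.cell_ids)]
        levels = list(pd.unique(lab))
        if len(levels) != 2:
            raise ValidationError(f"labels must have exactly 2 levels, got {levels}")
        self.group_a = group_a if group_a is not None else levels[0]
        self.group_b = group_b if group_b is not None else [l for l in levels if l != self.group_a][0]
        if set(levels) != {self.group_a, self.group_b}:
            raise ValidationError("group_a/group_b do not match label levels")
        n_a = int((lab == self.group_a).sum())
        n_b = int((lab == self.group_b).sum())
        if min(n_a, n_b) < 2:
            raise ValidationError("need at least 2 cells per group")
        self.counts = sub
        self.sf = size_factors.loc[list(sub.cell_ids)].to_numpy(dtype=float)
        self.is_b = (lab == self.group_b).to_numpy()
        self.prior_var = prior_var

    def fit(
        self, log2fc_threshold: float = 1.0, padj_threshold: float = 0.05
    ) -> DEResults:
        X = self.counts.values.astype(float)
        offset = np.log(self.sf)
        exog = np.column_stack([np.ones(X.shape[1]), self.is_b.astype(float)])
        norm_counts = X / self.sf[None, :]
        base_mean = norm_counts.mean(axis=1)
        tested = base_mean > 0
        n_skipped = int((~tested).sum())
        if n_skipped:
            logger.info("%d all-zero genes excluded", n_skipped)

        idx = np.where(tested)[0]
        mus = np.empty((len(idx), X.shape[1]))
        alpha_gw = np.empty(len(idx))
        for pos, g in enumerate(idx):
            y = X[g]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pois = sm.GLM(
                        y, exog, family=sm.families.Poisson(), offset=offset
                    ).fit(maxiter=100)
                mu = np.clip(pois.mu, 1e-8, None)
            except Exception:
                mu = np.clip(
                    np.where(self.is_b, y[self.is_b].mean(), y[~self.is_b].mean()),
                    1e-8,
                    None,
                )
            mus[pos] = mu
            alpha_gw[pos] = _dispersion_mle(y, mu, n_params=2)

        a_tr, b_tr = _fit_dispersion_trend(base_mean[tested], alpha_gw)
        alpha_trend = np.clip(a_tr / np.maximum(base_mean[tested], 1e-8) + b_tr,
                              _MIN_ALPHA, _MAX_ALPHA)
        # empirical-Bayes shrink in log space with fixed prior variance;
        # sampling variance of log dispersion approximated by trigamma
        m = X.shape[1]
        samp_var = float(special.polygamma(1, max((m - 2) / 2.0, 0.5)))
        w = self.prior_var / (self.prior_var + samp_var)
        alpha_shr = np.exp(
            w * np.log(np.maximum(alpha_gw, _MIN_ALPHA))
            + (1 - w) * np.log(alpha_trend)
        )

        log2fc = np.full(len(idx), np.nan)
        se = np.full(len(idx), np.nan)
        pval = np.full(len(idx), np.nan)
        converged = np.ones(len(idx), dtype=bool)
        for pos, g in enumerate(idx):
            y = X[g]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    nb = sm.GLM(
                        y,
                        exog,
                        family=sm.families.NegativeBinomial(alpha=float(alpha_shr[pos])),
                        offset=offset,
                    ).fit(maxiter=100)
                coef, bse = nb.params[1], nb.bse[1]
                if not (np.isfinite(coef) and np.isfinite(bse) and bse > 0):
                    raise RuntimeError
                if bse > _SE_LOG_CAP:  # separation: one group (nearly) all zero
                    converged[pos] = False
                    coef, bse = _moderated_wald(y, self.sf, self.is_b, float(alpha_shr[pos]))
            except Exception:
                converged[pos] = False
                coef, bse = _moderated_wald(y, self.sf, self.is_b, float(alpha_shr[pos]))
            log2fc[pos] = coef / _LN2
            se[pos] = bse / _LN2 if np.isfinite(bse) else np.nan
            z = coef / bse if np.isfinite(bse) and bse > 0 else np.nan
            pval[pos] = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan

        frame = pd.DataFrame(
            {
                "gene": self.counts.feature_ids[tested],
                "baseMean": base_mean[tested],
                "log2FC": log2fc,
                "se": se,
                "wald_p": pval,
                "dispersion": alpha_shr,
                "converged": converged,
            }
        )
        has_p = frame["wald_p"].notna()
        padj = np.full(len(frame), np.nan)
        if has_p.any():
            padj[has_p.to_numpy()] = multipletests(
                frame.loc[has_p, "wald_p"].to_numpy(), method="fdr_bh"
            )[1]
        frame["padj"] = padj
        frame["significant"] = (
            (frame["log2FC"].abs() > log2fc_threshold) & (frame["padj"] < padj_threshold)
        ).fillna(False)
        return DEResults(
            frame=frame,
            group_a=self.group_a,
            group_b=self.group_b,
            log2fc_threshold=log2fc_threshold,
            padj_threshold=padj_threshold,
        )


def nb_wald_de(
    counts: CountMatrix,
    size_factors: pd.Series,
    labels: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
    log2fc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> DEResults:
    """Functional wrapper around :class:`NegativeBinomialDE`."""
    model = NegativeBinomialDE(counts, size_factors, labels, group_a, group_b)
    return model.fit(log2fc_threshold, padj_threshold)


def filter_significant(
    table: pd.DataFrame, log2fc: float = 1.0, padj: float = 0.05
) -> pd.DataFrame:
    """Rows meeting |log2FC| > log2fc and padj < padj, with direction labels.

    Direction is relative to the comparison (second) group: positive log2FC
    is "up".
    """
    keep = (table["log2FC"].abs() > log2fc) & (table["padj"] < padj)
    out = table.loc[keep.fillna(False)].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out
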