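import numpy as np
import pandas as pd
import pytest

import scnoise as sn
from scnoise.io import ValidationError
from tests.conftest import make_norm


def two_cell_norm(x1, x2, s1, s2):
    """Two-cell matrix with given endogenous and spike-in log2 vectors."""
    values = np.vstack(
        [np.column_stack([x1, x2]), np.column_stack([s1, s2])]
    )
    n_endo = len(x1)
    ids = [f"g{i}" for i in range(n_endo)] + [f"ERCC-{i:05d}" for i in range(len(s1))]
    return make_norm(values, ids, ["cellA", "cellB"])


META2 = pd.DataFrame(
    {"cell_id": ["cellA", "cellB"], "age_group": "16h", "generation": [3, 7]}
)


class TestCellNoiseRatio:
    def test_cell_equal_to_group_mean_has_zero_b(self):
        x = np.array([1.0, 2.0, 3.0])
        s = np.array([2.0, 1.0, 3.0])
        norm = two_cell_norm(x, x, s, s)
        out = sn.cell_noise_ratio(norm, META2, min_detect_cells=1)
        np.testing.assert_allclose(out["b"], 0.0, atol=1e-12)

    def test_hand_computed_pearson(self):
        # group mean u = (1,3,2); cell A = (1,2,3) -> cor = 0.5 -> b = 0.5
        x1 = np.array([1.0, 2.0, 3.0])
        x2 = np.array([1.0, 4.0, 1.0])
        s = np.array([1.0, 2.0, 4.0])
        norm = two_cell_norm(x1, x2, s, s)
        out = sn.cell_noise_ratio(norm, META2, min_detect_cells=1)
        assert out.loc[out["cell_id"] == "cellA", "b"].item() == pytest.approx(0.5)

    def test_anticorrelated_spikeins_give_t_two(self):
        x = np.array([1.0, 2.0, 3.0])
        u = np.array([1.0, 2.0, 3.0])
        s1 = 6.0 - 2.0 * u  # cor(s1, mean) = -1
        s2 = 2.0 * u - s1
        norm = two_cell_norm(x, x, s1, s2)
        out = sn.cell_noise_ratio(norm, META2, min_detect_cells=1, t_tolerance=1e-9)
        # mean spike vector is u itself; cell A anti-correlates exactly
        assert out.loc[out["cell_id"] == "cellA", "t"].item() == pytest.approx(2.0)

    def test_affine_invariance_of_b_and_t(self, default_bundle):
        norm = default_bundle["norm"]
        meta = default_bundle["meta"]
        base = sn.cell_noise_ratio(norm, meta)
        shifted = sn.NormalizedMatrix(
            norm.values * 3.0 + 7.0,
            norm.feature_ids,
            norm.cell_ids,
            norm.is_spikein,
            norm.pseudocount,
        )
        # positive affine maps leave Pearson, hence b and t, unchanged;
        # fix the detection scope to make the gene sets identical
        keep = norm.endogenous().detected().sum(axis=1) >= 5
        scoped = norm.endogenous().subset_features(keep)
        scoped_shift = shifted.endogenous().subset_features(keep)
        spike = norm.spikeins()
        rebuilt = sn.NormalizedMatrix(
            np.vstack([scoped.values, spike.values]),
            np.concatenate([scoped.feature_ids, spike.feature_ids]),
            norm.cell_ids,
            np.concatenate([np.zeros(scoped.values.shape[0], bool), np.ones(spike.values.shape[0], bool)]),
            norm.pseudocount,
        )
        rebuilt_shift = sn.NormalizedMatrix(
            np.vstack([scoped_shift.values, spike.values * 3.0 + 7.0]),
            rebuilt.feature_ids,
            norm.cell_ids,
            rebuilt.is_spikein,
            norm.pseudocount,
        )
        a = sn.cell_noise_ratio(rebuilt, meta, min_detect_cells=1)
        b = sn.cell_noise_ratio(rebuilt_shift, meta, min_detect_cells=1)
        np.testing.assert_allclose(a["b"], b["b"], atol=1e-10)
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-10)


class TestCompareGroupNoise:
    def test_exact_two_sided_p_for_extreme_split(self):
        est = pd.DataFrame(
            {
                "age_group": ["a"] * 3 + ["b"] * 3,
                "ratio": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        out = sn.compare_group_noise(est, "a", "b")
        assert out["p"] == pytest.approx(0.1)

    def test_all_tied_values_give_p_one(self):
        est = pd.DataFrame({"age_group": ["a"] * 3 + ["b"] * 3, "ratio": [2.0] * 6})
        with pytest.warns(UserWarning, match="tied"):
            out = sn.compare_group_noise(est, "a", "b")
        assert out["p"] == 1.0


class TestTechnicalFit:
    def test_exact_interpolation_of_two_species(self):
        # constructed multisets give exact means/CV^2; with two species the
        # model interpolates and must match the closed-form line
        m = 100
        a = np.concatenate([np.full(m // 2, 5), np.full(m // 2, 15)])  # mu=10
        b = np.concatenate([np.full(m // 2, 70), np.full(m // 2, 130)])  # mu=100
        cm = sn.CountMatrix(
            np.vstack([a, b]), ["ERCC-00001", "ERCC-00002"], [f"c{i}" for i in range(m)]
        )
        sf = pd.Series(np.ones(m), index=cm.cell_ids)
        mu = np.array([10.0, 100.0])
        cv2 = np.array([a.var(ddof=1) / 100.0, b.var(ddof=1) / 10000.0])
        a1_expected = (cv2[0] - cv2[1]) / (1 / mu[0] - 1 / mu[1])
        alpha0_expected = cv2[1] - a1_expected / mu[1]
        fit = sn.fit_technical_cv2(cm, sf, fit_quantile=0.0)
        assert fit.a1 == pytest.approx(a1_expected, rel=1e-6)
        assert fit.alpha0 == pytest.approx(alpha0_expected, rel=1e-6)
        assert fit.n_spikeins_fit == 2

    def test_single_species_above_floor_is_error(self):
        m = 10
        values = np.vstack([np.full(m, 50), np.zeros(m, int)])
        cm = sn.CountMatrix(values, ["ERCC-00001", "ERCC-00002"], [f"c{i}" for i in range(m)])
        sf = pd.Series(np.ones(m), index=cm.cell_ids)
        with pytest.raises(ValidationError):
            sn.fit_technical_cv2(cm, sf, fit_quantile=0.9)

    def test_poisson_spikeins_recover_unit_slope_and_zero_offset(self):
        design = sn.SimulationDesign(
            nb_dispersion=0.0,
            extrinsic_sd={"2h": 0.0, "16h": 0.0, "36h": 0.0},
            n_hvgs=0,
            marker_correlations=(),
            planted_tf=None,
        )
        sim = sn.simulate_experiment(design, seed=11)
        sf_spike = sn.size_factors(sim.counts, feature_scope="spikein")
        fit = sn.fit_technical_cv2(sim.counts.spikeins(), sf_spike)
        assert fit.alpha0 <= 0.02
        assert 0.8 <= fit.a1 <= 1.3  # near-Poisson CV^2 = 1/mu in normalized units


class TestHvgTest:
    @staticmethod
    def _constant_variance_gene(mean, half_spread, m=50):
        return np.concatenate(
            [np.full(m // 2, mean - half_spread), np.full(m // 2, mean + half_spread)]
        )

    def test_chi_square_statistic_matches_oracle(self):
        # mu = 100, cv2 = 0.5 exactly (25x30, 25x170), m = 50 cells
        y = self._constant_variance_gene(100, 70)
        cm = sn.CountMatrix(y[None, :], ["g1"], [f"c{i}" for i in range(50)])
        sf = pd.Series(np.ones(50), index=cm.cell_ids)
        fit = sn.TechnicalFit(a1=2.0, alpha0=0.1, fit_domain=0.0, n_spikeins_fit=10)
        out = sn.hvg_test(cm, sf, fit, min_biol_cv2=0.25, psi=1.0)
        row = out.iloc[0]
        assert row["cv2"] == pytest.approx(0.5)
        # null CV^2 = 2/100 + 0.1 + 0.25 * 1.1 = 0.395
        assert row["chi2_stat"] == pytest.approx(49 * 0.5 / 0.395)
        assert row["p"] == pytest.approx(0.10018532466491474, rel=1e-9)

    def test_low_biological_cv2_never_flagged(self):
        y = self._constant_variance_gene(100, 10)  # cv2 ~ 0.0102 < technical
        cm = sn.CountMatrix(y[None, :], ["g1"], [f"c{i}" for i in range(50)])
        sf = pd.Series(np.ones(50), index=cm.cell_ids)
        fit = sn.TechnicalFit(a1=2.0, alpha0=0.1, fit_domain=0.0, n_spikeins_fit=10)
        out = sn.hvg_test(cm, sf, fit)
        assert out.iloc[0]["cv2_biol"] < 0
        assert not out.iloc[0]["is_hvg"]

    def test_bh_adjustment_is_monotone_in_p(self, default_bundle):
        sim = default_bundle["sim"]
        sf_spike = sn.size_factors(sim.counts, feature_scope="spikein")
        fit = sn.fit_technical_cv2(sim.counts.spikeins(), sf_spike)
        out = sn.hvg_test(sim.counts.endogenous(), default_bundle["sf"], fit)
        ordered = out.sort_values("p")
        assert ordered["fdr"].is_monotonic_increasing
        assert out["p"].between(0, 1).all() and out["fdr"].between(0, 1).all()

    def test_planted_hvgs_recovered(self):
        design = sn.SimulationDesign(
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
        sim = sn.simulate_experiment(design, seed=3)
        sf_spike = sn.size_factors(sim.counts, feature_scope="spikein")
        fit = sn.fit_technical_cv2(sim.counts.spikeins(), sf_spike)
        sf = sn.size_factors(sim.counts)
        out = sn.hvg_test(sim.counts.endogenous(), sf, fit)
        report = sn.evaluate_recovery(sim.truth, hvg_frame=out)
        assert report.values["hvg_sensitivity"] >= 0.8
        assert report.values["hvg_fdr"] <= 0.15


class TestMeanCv2Trend:
    def test_poisson_limit_slope(self):
        rng = np.random.default_rng(0)
        mu = np.geomspace(2, 2000, 300)
        X = rng.poisson(mu[:, None], size=(300, 400))
        fit = sn.mean_cv2_trend(X, floor=1.0)
        assert fit.slope == pytest.approx(-1.0, abs=0.05)
        assert abs(fit.intercept) < 0.1

    def test_extrinsic_noise_raises_high_expression_cv2(self):
        rng = np.random.default_rng(1)
        mu = np.geomspace(2, 2000, 300)
        X_pois = rng.poisson(mu[:, None], size=(300, 400))
        lam = mu[:, None] * rng.lognormal(0.0, 0.5, size=(300, 400))
        X_noisy = rng.poisson(lam)
        f0 = sn.mean_cv2_trend(X_pois, floor=1.0)
        f1 = sn.mean_cv2_trend(X_noisy, floor=1.0)
        assert f1.predict_cv2(1000.0) > f0.predict_cv2(1000.0)

    def test_identical_input_identical_fit(self, default_bundle):
        counts = default_bundle["counts"].endogenous()
        lin = counts.values / default_bundle["sf"].to_numpy()[None, :]
        f1 = sn.mean_cv2_trend(lin, group="a")
        f2 = sn.mean_cv2_trend(lin, group="b")
        assert (f1.slope, f1.intercept, f1.n_genes) == (f2.slope, f2.intercept, f2.n_genes)

    def test_too_few_genes_above_floor_is_error(self):
        X = np.random.default_rng(2).poisson(0.01, size=(50, 20))
        with pytest.raises(ValidationError):
            sn.mean_cv2_trend(X, floor=10.0)
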