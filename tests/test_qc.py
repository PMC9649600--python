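import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scnoise as sn
from scnoise.io import ValidationError


def build_counts_with_metrics(metrics):
    """Cells with prescribed (genes_detected, total_mapped_reads, ercc_frac).

    genes_detected is realized by flagging that many endogenous genes with a
    single read; total_mapped_reads is carried in the metadata and the single
    spike-in row is set to ercc_frac * total reads.
    """
    n_genes = 2500
    n = len(metrics)
    endo = np.zeros((n_genes, n), dtype=int)
    spike = np.zeros((1, n), dtype=int)
    total = []
    for j, (genes, reads, frac) in enumerate(metrics):
        endo[:genes, j] = 1
        spike[0, j] = int(round(frac * reads))
        total.append(reads)
    values = np.vstack([endo, spike])
    ids = [f"g{i}" for i in range(n_genes)] + ["ERCC-00001"]
    cm = sn.CountMatrix(values, ids, [f"c{j + 1}" for j in range(n)])
    meta = pd.DataFrame(
        {
            "cell_id": cm.cell_ids,
            "age_group": "16h",
            "generation": 5,
            "total_mapped_reads": total,
        }
    )
    return cm, meta


class TestQcFilter:
    def test_three_rules_applied_jointly(self):
        # each cell violates exactly one threshold except cells 1 and 5
        metrics = [
            (1200, 50_000, 0.2),
            (800, 50_000, 0.2),
            (1200, 30_000, 0.2),
            (1200, 50_000, 0.8),
            (2000, 100_000, 0.1),
        ]
        cm, meta = build_counts_with_metrics(metrics)
        out = sn.qc_filter(cm, meta)
        assert out["qc_pass"].tolist() == [True, False, False, False, True]

    @pytest.mark.parametrize(
        "metrics,expected",
        [
            ((999, 50_000, 0.5), False),  # one gene short
            ((1000, 40_000, 0.74), True),  # exactly at every threshold
            ((1500, 60_000, 0.75), False),  # ERCC fraction just above
        ],
    )
    def test_thresholds_are_boundaries(self, metrics, expected):
        cm, meta = build_counts_with_metrics([metrics])
        out = sn.qc_filter(cm, meta)
        assert bool(out.loc[0, "qc_pass"]) is expected

    def test_unknown_cell_reported(self, tiny_counts):
        meta = pd.DataFrame(
            {"cell_id": ["c1", "ghost"], "age_group": "2h", "generation": 1}
        )
        with pytest.raises(ValidationError, match="ghost"):
            sn.qc_filter(tiny_counts, meta)


class TestSizeFactors:
    def test_proportional_cells_identity(self):
        a = np.array([10, 4, 6])
        cm = sn.CountMatrix(np.column_stack([a, 2 * a]), ["g1", "g2", "g3"], ["A", "B"])
        sf = sn.size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_cells_give_unit_factors(self):
        cm = sn.CountMatrix(np.tile([[5], [9]], (1, 4)), ["g1", "g2"], list("abcd"))
        np.testing.assert_allclose(sn.size_factors(cm).to_numpy(), np.ones(4))

    def test_hand_computed_median_of_ratios(self, tiny_counts):
        # ratios cell1: 10/sqrt(200), 4/4, 6/sqrt(108) -> median 10/sqrt(200)
        sf = sn.size_factors(tiny_counts)
        np.testing.assert_allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.5, 8.0),
    )
    def test_permutation_and_scale_invariance(self, seed, scale_num):
        rng = np.random.default_rng(seed)
        values = rng.poisson(20, size=(15, 6)) + 1
        cm = sn.CountMatrix(values, [f"g{i}" for i in range(15)], list("abcdef"))
        sf = sn.size_factors(cm)
        # permuting cells permutes factors
        perm = rng.permutation(6)
        cm_p = sn.CountMatrix(values[:, perm], cm.feature_ids, np.asarray(cm.cell_ids)[perm])
        pd.testing.assert_series_equal(sn.size_factors(cm_p).sort_index(), sf.sort_index())
        # multiplying the whole matrix by an integer constant changes nothing
        k = max(int(scale_num), 1)
        cm_s = sn.CountMatrix(values * k, cm.feature_ids, cm.cell_ids)
        np.testing.assert_allclose(sn.size_factors(cm_s).to_numpy(), sf.to_numpy(), rtol=1e-10)

    def test_geometric_mean_is_one(self, default_bundle):
        sf = default_bundle["sf"].to_numpy()
        assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0)

    def test_no_common_feature_requires_poscounts(self):
        values = np.array([[5, 0], [0, 7]])
        cm = sn.CountMatrix(values, ["g1", "g2"], ["a", "b"])
        with pytest.raises(ValidationError, match="poscounts"):
            sn.size_factors(cm)
        sf = sn.size_factors(cm, poscounts=True)
        assert (sf > 0).all()

    def test_recovers_known_depth_multipliers(self, default_sim):
        sf = sn.size_factors(default_sim.counts, feature_scope="endogenous")
        report = sn.evaluate_recovery(default_sim.truth, size_factors=sf)
        assert report.values["size_factor_median_rel_error"] <= 0.05


class TestNormalizeLog2:
    def test_formula_values(self):
        cm = sn.CountMatrix(np.array([[0], [7]]), ["g1", "g2"], ["A"])
        sf = pd.Series([1 / np.sqrt(2)], index=["A"])
        norm = sn.normalize_log2(cm, sf, pseudocount=1.0)
        assert norm.values[0, 0] == 0.0
        np.testing.assert_allclose(norm.values[1, 0], np.log2(7 * np.sqrt(2) + 1))
        assert np.isclose(norm.values[1, 0], 3.446, atol=1e-3)

    def test_scale_invariance_of_count_and_factor(self):
        cm1 = sn.CountMatrix(np.array([[6]]), ["g"], ["A"])
        cm2 = sn.CountMatrix(np.array([[12]]), ["g"], ["A"])
        v1 = sn.normalize_log2(cm1, pd.Series([0.5], index=["A"])).values
        v2 = sn.normalize_log2(cm2, pd.Series([1.0], index=["A"])).values
        np.testing.assert_allclose(v1, v2)

    def test_missing_size_factor_is_error(self, tiny_counts):
        with pytest.raises(ValidationError, match="c2"):
            sn.normalize_log2(tiny_counts, pd.Series([1.0], index=["c1"]))


class TestTpm:
    def test_single_expressed_gene_gets_million(self):
        cm = sn.CountMatrix(np.array([[8], [0]]), ["g1", "g2"], ["A"])
        out = sn.tpm(cm, np.array([500.0, 700.0]))
        assert out.loc["g1", "A"] == pytest.approx(1e6)

    def test_length_normalization(self):
        cm = sn.CountMatrix(np.array([[10], [10]]), ["g1", "g2"], ["A"])
        out = sn.tpm(cm, np.array([1000.0, 2000.0]))
        np.testing.assert_allclose(out["A"].to_numpy(), [2e6 / 3, 1e6 / 3])

    def test_all_zero_cell_stays_zero(self):
        cm = sn.CountMatrix(np.zeros((2, 1), int), ["g1", "g2"], ["A"])
        out = sn.tpm(cm, np.array([1000.0, 1000.0]))
        assert (out["A"] == 0).all() and out.notna().all().all()

    def test_nonpositive_length_rejected(self, tiny_counts):
        with pytest.raises(ValidationError):
            sn.tpm(tiny_counts, np.array([1000.0, 0.0, 1000.0]))
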