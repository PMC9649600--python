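from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import scnoise as sn
from scnoise.io import GeneSetCollection
from scnoise.regulon import ranksum_pvalue_greater
from tests.conftest import make_norm


def brute_force_p(values, target_mask):
    """Independent enumeration oracle for the one-sided rank-sum null."""
    from scipy.stats import rankdata

    ranks = rankdata(values)
    w_obs = ranks[target_mask].sum()
    k = int(target_mask.sum())
    hits = total = 0
    for subset in combinations(range(len(values)), k):
        total += 1
        if ranks[list(subset)].sum() >= w_obs - 1e-9:
            hits += 1
    return hits / total


class TestRanksumPvalue:
    def test_top_ranked_targets_exact_p(self):
        # 3 targets occupying the top 3 of 10 ranks: p = 1 / C(10,3) = 1/120,
        # so a small set can never reach the 1e-4 activity threshold
        values = np.arange(1.0, 11.0)
        mask = np.zeros(10, dtype=bool)
        mask[-3:] = True
        _, p = ranksum_pvalue_greater(values, mask)
        assert p == pytest.approx(1 / 120)
        assert p > 1e-4

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(2, n - 1))
        values = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        _, p = ranksum_pvalue_greater(values, mask)
        assert p == pytest.approx(brute_force_p(values, mask), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 10, size=200)
        mask = np.zeros(200, dtype=bool)
        mask[rng.choice(200, 40, replace=False)] = True
        _, p1 = ranksum_pvalue_greater(values, mask)
        _, p2 = ranksum_pvalue_greater(np.exp(values) + 5.0, mask)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestIntersectHits:
    def test_examples(self):
        assert sn.intersect_hits(["A", "B", "C"], ["B", "C"], ["C"]) == ["C"]
        assert sn.intersect_hits(["A", "B"], [], ["A"]) == []

    def test_order_follows_first_list(self):
        assert sn.intersect_hits(["B", "A"], ["A", "B"], ["A", "B"]) == ["B", "A"]


def _subgroup_norm(shift, n_targets=8, n_genes=40, n_cells=12, sigma=0.3, seed=0):
    """S/F cells where targets are shifted up by `shift` log2 units in F."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(2, 6, size=n_genes)
    values = base[:, None] + rng.normal(0, sigma, size=(n_genes, n_cells))
    half = n_cells // 2
    values[:n_targets, half:] += shift
    ids = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    norm = make_norm(values, ids, cells)
    assignment = pd.DataFrame(
        {
            "cell_id": cells,
            "age_group": "16h",
            "generation": [2] * half + [7] * half,
            "subgroup": ["S"] * half + ["F"] * half,
        }
    )
    sets = GeneSetCollection({"TF1": frozenset(ids[:n_targets])})
    return norm, assignment, sets


class TestApproach1:
    def test_constructed_two_unit_shift(self):
        norm, assignment, sets = _subgroup_norm(shift=2.0)
        out = sn.approach1_median_shift(norm, assignment, sets, min_members=3)
        row = out.iloc[0]
        assert row["log2fc"] == pytest.approx(2.0, abs=0.5)
        assert row["passed"]

    def test_identical_subgroups_fail(self):
        norm, assignment, sets = _subgroup_norm(shift=0.0)
        out = sn.approach1_median_shift(norm, assignment, sets, min_members=3)
        assert out.iloc[0]["log2fc"] == pytest.approx(0.0, abs=0.5)
        assert not out.iloc[0]["passed"]

    def test_small_sets_are_skipped(self):
        norm, assignment, _ = _subgroup_norm(shift=2.0)
        sets = GeneSetCollection({"TINY": frozenset(["g0", "g1"])})
        out = sn.approach1_median_shift(norm, assignment, sets, min_members=5)
        assert len(out) == 0


class TestApproach2:
    def test_null_targets_rarely_on(self, default_bundle):
        sim = default_bundle["sim"]
        assign = sn.split_subgroups(default_bundle["meta"], "16h")
        decoys = {
            tf: members
            for tf, members in sim.gene_sets.items()
            if tf.startswith("TF_DECOY")
        }
        activity, table = sn.approach2_percell_activity(
            default_bundle["norm"], assign, GeneSetCollection(decoys)
        )
        on_rate = activity["active"].dropna().mean()
        assert on_rate < 0.01

    def test_planted_induction_passes(self, default_bundle):
        sim = default_bundle["sim"]
        assign = sn.split_subgroups(default_bundle["meta"], "16h")
        planted = GeneSetCollection({sim.truth.regulon_tf: sim.gene_sets[sim.truth.regulon_tf]})
        _, table = sn.approach2_percell_activity(default_bundle["norm"], assign, planted)
        assert table.iloc[0]["frac_on_F"] > table.iloc[0]["frac_on_S"]
        assert table.iloc[0]["passed"]


class TestApproach3:
    def test_summary_proportional_to_generation(self):
        norm, assignment, sets = _subgroup_norm(shift=0.0, sigma=0.0)
        # make every target's expression equal to the generation itself
        gens = assignment["generation"].to_numpy(dtype=float)
        norm.values[:8, :] = gens[None, :]
        meta = assignment[["cell_id", "age_group", "generation"]]
        out = sn.approach3_generation_cor(norm, meta, sets, "16h", min_members=3)
        assert out.iloc[0]["R"] == pytest.approx(1.0)
        assert out.iloc[0]["passed"]


class TestFullProcedure:
    def test_planted_regulon_is_sole_final_hit(self, default_bundle):
        sim = default_bundle["sim"]
        assign = sn.split_subgroups(default_bundle["meta"], "16h")
        comp = sn.compare_regulons(
            default_bundle["norm"], default_bundle["meta"], assign, sim.gene_sets, "16h"
        )
        assert comp.final_hits == [sim.truth.regulon_tf]
        table = comp.table.set_index("tf")
        # final hits are a subset of approach-1 hits which are a subset of TFs
        assert set(comp.final_hits) <= set(table.index[table["a1_passed"]])
        assert "final (1 & 2 & 3)" in comp.summary()
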