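import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from osteoscreen.hits import (
    DegenerateDataError,
    HitCallingError,
    bonferroni_adjust,
    intersect_categories,
    make_enrichment_export,
    osteo_score,
    partition_categories,
    permutation_t_test,
    select_secondary_candidates,
)


def brute_force_permutation_p(x, y):
    """Independent enumeration oracle using scipy's pooled t statistic."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    t_obs = stats.ttest_ind(x, y, equal_var=True).statistic
    count = 0
    combos = list(itertools.combinations(range(len(pooled)), nx))
    for combo in combos:
        xi = pooled[list(combo)]
        yi = pooled[[i for i in range(len(pooled)) if i not in combo]]
        t = stats.ttest_ind(xi, yi, equal_var=True).statistic
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return count / len(combos)


class TestOsteoScore:
    @pytest.mark.parametrize("raw,viab,expected", [(2.0, 1.0, 2.0), (1.5, 0.5, 3.0)])
    def test_ratio(self, raw, viab, expected):
        assert osteo_score(raw, viab) == expected

    def test_nonpositive_viability_rejected(self):
        with pytest.raises(HitCallingError):
            osteo_score(1.0, 0.0)

    def test_replicate_wise_ratio(self):
        runx2 = np.array([2.0, 2.0, 2.0])
        viab = np.array([1.0, 2.0, 4.0])
        assert np.allclose(runx2 / viab, [2.0, 1.0, 0.5])


class TestPartitionCategories:
    def test_positive_tail_only(self):
        scores = {f"g{i}": 1.0 + i / 10 for i in range(1, 11)}  # all above 1
        part = partition_categories(scores)
        assert len(part.UR) == 4  # floor(0.4 * 10)
        assert len(part.DR) == 0
        assert len(part.NC) == 6
        assert part.UR == {"g7", "g8", "g9", "g10"}

    def test_all_at_reference_all_nc(self):
        scores = {f"g{i}": 1.0 for i in range(5)}
        part = partition_categories(scores)
        assert part.UR == frozenset() and part.DR == frozenset()
        assert len(part.NC) == 5

    def test_symmetric_tails(self):
        scores = {f"u{i}": 2.0 + i * 0.01 for i in range(5)}
        scores.update({f"d{i}": 0.5 - i * 0.01 for i in range(5)})
        part = partition_categories(scores)
        assert len(part.UR) == 2 and len(part.DR) == 2  # floor(0.4*5) per tail
        assert len(part.NC) == 6

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(5)
        scores = {f"g{i:03d}": float(v) for i, v in enumerate(rng.lognormal(0, 0.5, 200))}
        part = partition_categories(scores)
        assert part.UR | part.DR | part.NC == set(scores)
        assert not (part.UR & part.DR or part.UR & part.NC or part.DR & part.NC)
        assert all(scores[g] > 1.0 for g in part.UR)
        assert all(scores[g] < 1.0 for g in part.DR)

    def test_order_equivariance(self):
        rng = np.random.default_rng(6)
        items = [(f"g{i:03d}", float(v)) for i, v in enumerate(rng.lognormal(0, 0.5, 50))]
        p1 = partition_categories(dict(items))
        p2 = partition_categories(dict(reversed(items)))
        assert p1.UR == p2.UR and p1.DR == p2.DR and p1.NC == p2.NC

    def test_empty_rejected(self):
        with pytest.raises(HitCallingError):
            partition_categories({})


class TestIntersectCategories:
    def _part(self, ur, dr, nc, topo):
        from osteoscreen.hits import CategoryPartition

        return CategoryPartition(
            topography=topo,
            UR=frozenset(ur),
            DR=frozenset(dr),
            NC=frozenset(nc),
        )

    def test_set_algebra(self):
        f = self._part({"a", "b", "c"}, set(), set(), "fiber")
        s = self._part({"b", "c", "d"}, set(), set(), "smooth")
        inter = intersect_categories(f, s)
        assert inter.both["UR"] == {"b", "c"}
        assert inter.fiber_only["UR"] == {"a"}
        assert inter.smooth_only["UR"] == {"d"}

    def test_identical_partitions_no_exclusives(self):
        f = self._part({"a"}, {"b"}, {"c"}, "fiber")
        inter = intersect_categories(f, f)
        for cat in ("UR", "DR", "NC"):
            assert inter.fiber_only[cat] == frozenset()
            assert inter.smooth_only[cat] == frozenset()

    def test_disjoint_partitions_empty_both(self):
        f = self._part({"a"}, set(), set(), "fiber")
        s = self._part({"b"}, set(), set(), "smooth")
        inter = intersect_categories(f, s)
        assert inter.both["UR"] == frozenset()
        venn = inter.venn_summary()
        assert set(venn["category"]) == {"UR", "DR", "NC"}


class TestPermutationTTest:
    def test_separated_groups_minimum_p(self):
        res = permutation_t_test([10, 11, 12], [1, 2, 3], mode="exhaustive")
        assert res.B == 20
        assert res.n_extreme == 2  # original labeling and its mirror
        assert res.p_perm == pytest.approx(0.1)

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(0, 1, 3)
            y = rng.normal(0.5, 1, 3)
            res = permutation_t_test(x, y, mode="exhaustive")
            assert res.p_perm == brute_force_permutation_p(x, y)

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 3)
        y = rng.normal(1.0, 1, 3)
        exact = permutation_t_test(x, y, mode="exhaustive").p_perm
        mc = permutation_t_test(x, y, B=100_000, seed=0, mode="monte_carlo")
        assert mc.p_perm == pytest.approx(exact, abs=0.01)

    def test_null_data_large_p(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 3)
        y = x.copy()  # identical groups: t_obs = 0, every |t(b)| >= 0
        res = permutation_t_test(x, y, B=1000, seed=1, mode="monte_carlo")
        assert res.t_obs == 0.0
        assert res.p_perm == 1.0

    def test_auto_mode_selects_exhaustive_for_3v3(self):
        res = permutation_t_test([1.0, 2.0, 3.5], [2.5, 0.5, 3.0])
        assert res.mode == "exhaustive"

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(DegenerateDataError, match="degenerate|identical"):
            permutation_t_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        with pytest.raises(HitCallingError):
            permutation_t_test([1.0], [2.0, 3.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_p_in_unit_interval_and_deterministic(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 3)
        y = rng.normal(0, 1, 3)
        r1 = permutation_t_test(x, y, B=200, seed=seed, mode="monte_carlo")
        r2 = permutation_t_test(x, y, B=200, seed=seed, mode="monte_carlo")
        assert 0.0 <= r1.p_perm <= 1.0
        assert r1.p_perm == r2.p_perm


class TestBonferroni:
    @pytest.mark.parametrize(
        "pvals,expected",
        [([0.01], [0.01]), ([0.01] * 5, [0.05] * 5), ([0.4] * 5, [1.0] * 5)],
    )
    def test_examples(self, pvals, expected):
        assert bonferroni_adjust(pvals) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(HitCallingError):
            bonferroni_adjust([0.5, 1.2])


class TestSecondaryCandidates:
    def _partition_with_scores(self, n_ur=30, n_dr=5, n_nc=10):
        scores = {}
        scores.update({f"u{i:02d}": 2.0 + i * 0.1 for i in range(n_ur)})
        scores.update({f"d{i:02d}": 0.5 - i * 0.01 for i in range(n_dr)})
        scores.update({f"n{i:02d}": 1.0 + (i - 5) * 0.001 for i in range(n_nc)})
        from osteoscreen.hits import CategoryPartition

        part = CategoryPartition(
            topography="fiber",
            UR=frozenset(k for k in scores if k.startswith("u")),
            DR=frozenset(k for k in scores if k.startswith("d")),
            NC=frozenset(k for k in scores if k.startswith("n")),
        )
        return part, scores

    def test_floor_counts_and_floor_lift(self):
        part, scores = self._partition_with_scores()
        cands = select_secondary_candidates(part, scores)
        assert len(cands["UR"]) == 3  # floor(0.1*30)
        assert len(cands["DR"]) == 1  # floor(0.1*5)=0, lifted to 1
        assert cands["UR"] == ["u29", "u28", "u27"]  # highest scores
        assert cands["DR"] == ["d04"]  # lowest score

    def test_nc_candidates_closest_to_reference(self):
        part, scores = self._partition_with_scores()
        cands = select_secondary_candidates(part, scores)
        assert cands["NC"] == ["n05"]  # score exactly 1.0


class TestEnrichmentExport:
    def test_pseudo_values(self):
        table = make_enrichment_export(
            {"a": "UR", "b": "DR", "c": "NC", "d": "DR"}, significant={"a", "d"}
        )
        rows = {r.gene_id: (r.fold_change, r.p_value) for r in table.itertuples()}
        assert rows["a"] == (2.0, 0.00001)
        assert rows["b"] == (-2.0, 1.0)
        assert rows["c"] == (1.0, 1.0)
        assert rows["d"] == (-2.0, 0.00001)

    def test_uncategorized_gene_rejected(self):
        with pytest.raises(HitCallingError):
            make_enrichment_export({"a": "none"})
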