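import itertools
import math

import numpy as np
import pytest

from dapnet import (
    AssociationEstimate,
    DapRecord,
    ExpressionDataset,
    GenePairList,
    PairSelectionConfig,
    PermutationConfig,
    adaptive_permutation_test,
    fisher_z_transform,
    one_sample_fisher_z,
    permutation_test_difference,
    select_pairs_for_permutation,
    two_sample_fisher_z,
)


def _est(r, n, metric="pearson"):
    return AssociationEstimate(metric, r, n)


class TestFisherZTransform:
    def test_closed_form_values(self):
        assert fisher_z_transform(0.0) == 0.0
        assert fisher_z_transform(0.5) == pytest.approx(0.5493061443340548, abs=1e-12)
        assert fisher_z_transform(-0.5) == pytest.approx(-0.5493061443340548, abs=1e-12)

    def test_inflation_at_strong_correlations(self):
        z = fisher_z_transform
        assert z(0.95) - z(0.5) > z(0.5) - z(0.05)

    def test_clamping_near_one_warns(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = fisher_z_transform(1.0)
        assert math.isfinite(z)


class TestOneSampleFisherZ:
    def test_null_correlation(self):
        res = one_sample_fisher_z(_est(0.0, 25))
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_derived_value(self):
        res = one_sample_fisher_z(_est(0.5, 19))
        assert res.statistic == pytest.approx(2.197224577336219, abs=1e-9)
        assert res.p == pytest.approx(0.028004411147890085, abs=1e-9)

    def test_sign_flip_symmetry(self):
        pos = one_sample_fisher_z(_est(0.7, 12))
        neg = one_sample_fisher_z(_est(-0.7, 12))
        assert neg.statistic == pytest.approx(-pos.statistic)
        assert neg.p == pytest.approx(pos.p)

    def test_small_n_undefined(self):
        assert one_sample_fisher_z(_est(0.5, 3)) is None

    def test_non_pearson_rejected(self):
        with pytest.raises(ValueError):
            one_sample_fisher_z(_est(0.5, 19, metric="spearman"))


class TestTwoSampleFisherZ:
    def test_null_identity(self):
        res = two_sample_fisher_z(_est(0.4, 15), _est(0.4, 20))
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_derived_pearson_value(self):
        res = two_sample_fisher_z(_est(0.5, 19), _est(-0.5, 19))
        assert res.statistic == pytest.approx(3.1073447968483725, abs=1e-9)
        assert res.p == pytest.approx(0.0018877608021744049, abs=1e-9)

    def test_class_swap_antisymmetry(self):
        a, b = _est(0.8, 10), _est(0.2, 14)
        fwd, rev = two_sample_fisher_z(a, b), two_sample_fisher_z(b, a)
        assert rev.statistic == pytest.approx(-fwd.statistic)
        assert rev.p == pytest.approx(fwd.p)

    @pytest.mark.parametrize(
        "metric,n_min,var_num,deg",
        [("pearson", 4, 1.0, 3), ("spearman", 4, 1.06, 3), ("kendall", 5, 0.437, 4)],
    )
    def test_metric_specific_standard_errors(self, metric, n_min, var_num, deg):
        n1, n2 = 12, 18
        res = two_sample_fisher_z(_est(0.6, n1, metric), _est(0.1, n2, metric))
        se = math.sqrt(var_num / (n1 - deg) + var_num / (n2 - deg))
        expected = (math.atanh(0.6) - math.atanh(0.1)) / se
        assert res.statistic == pytest.approx(expected, abs=1e-12)
        assert two_sample_fisher_z(_est(0.6, n_min - 1, metric), _est(0.1, n2, metric)) is None

    def test_mi_directed_to_permutation(self):
        with pytest.raises(ValueError, match="permutation"):
            two_sample_fisher_z(_est(0.5, 20, "mi"), _est(0.2, 20, "mi"))


def _perm_dataset(npc, seed=5, r=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(8, 1, 2 * npc)
    y = r * (x - 8) + math.sqrt(1 - r * r) * rng.normal(0, 1, 2 * npc) + 8
    ds = ExpressionDataset(
        ["a", "b"],
        [f"s{i}" for i in range(2 * npc)],
        np.array(["A"] * npc + ["B"] * npc),
        np.vstack([x, y]),
    )
    return ds, np.zeros_like(ds.missing_mask)


def _exhaustive_oracle(x, y, npc):
    """Independent enumeration of all C(2n, n) label assignments."""
    def corr(ix):
        xs, ys = x[list(ix)], y[list(ix)]
        return float(np.corrcoef(xs, ys)[0, 1])

    universe = set(range(2 * npc))
    d_obs = corr(range(npc)) - corr(range(npc, 2 * npc))
    count = total = 0
    for c in itertools.combinations(range(2 * npc), npc):
        rest = sorted(universe - set(c))
        total += 1
        if abs(corr(c) - corr(rest)) >= abs(d_obs) - 1e-12:
            count += 1
    return count / total


class TestPermutationTest:
    @pytest.mark.parametrize("npc", [3, 4])
    def test_matches_exhaustive_enumeration(self, npc):
        ds, mask = _perm_dataset(npc)
        res = permutation_test_difference(ds, mask, ("a", "b"), "pearson", PermutationConfig(seed=1))
        oracle = _exhaustive_oracle(ds.values[0], ds.values[1], npc)
        assert res.p == pytest.approx(oracle, abs=1e-12)
        assert res.n_permutations == math.comb(2 * npc, npc)

    def test_cloned_classes_give_large_p(self):
        rng = np.random.default_rng(8)
        block = rng.normal(8, 1, (2, 12))
        ds = ExpressionDataset(
            ["a", "b"],
            [f"s{i}" for i in range(24)],
            np.array(["A"] * 12 + ["B"] * 12),
            np.hstack([block, block]),
        )
        mask = np.zeros_like(ds.missing_mask)
        cfg = PermutationConfig(B_max=500, seed=2, exhaustive=False)
        res = permutation_test_difference(ds, mask, ("a", "b"), "pearson", cfg)
        assert res.p > 0.5

    def test_add_one_lower_bound(self):
        ds, mask = _perm_dataset(10, seed=3, r=0.95)
        # make the two classes maximally different: destroy correlation in B
        ds.values[1, 10:] = np.random.default_rng(0).normal(8, 1, 10)
        cfg = PermutationConfig(B_max=200, seed=4, exhaustive=False)
        res = permutation_test_difference(ds, mask, ("a", "b"), "pearson", cfg)
        assert res.p >= 1 / 201

    def test_seeded_reproducibility(self):
        ds, mask = _perm_dataset(8, seed=6)
        cfg = PermutationConfig(B_max=300, seed=11, exhaustive=False)
        r1 = permutation_test_difference(ds, mask, ("a", "b"), "pearson", cfg)
        r2 = permutation_test_difference(ds, mask, ("a", "b"), "pearson", cfg)
        assert r1.p == r2.p and r1.statistic == r2.statistic

    @pytest.mark.parametrize("metric", ["spearman", "kendall", "mi"])
    def test_other_metrics_supported(self, metric):
        npc = 8 if metric == "mi" else 5
        ds, mask = _perm_dataset(npc, seed=7, r=0.5)
        cfg = PermutationConfig(B_max=100, seed=1, exhaustive=False)
        res = permutation_test_difference(ds, mask, ("a", "b"), metric, cfg)
        assert 0 < res.p <= 1


class TestAdaptivePermutation:
    def test_null_pair_stops_early(self):
        ds, mask = _perm_dataset(10, seed=12, r=0.0)
        cfg = PermutationConfig(B_max=10_000, adaptive=True, h_exceedances=10, seed=3)
        res = adaptive_permutation_test(ds, mask, ("a", "b"), "pearson", cfg)
        assert res.n_permutations < 2000
        assert res.p == pytest.approx(10 / res.n_permutations)

    def test_extreme_pair_runs_to_budget(self):
        # r = +1 in class A, -1 in class B: only the identity/complement
        # splits reach |d_obs| = 2, so no random exceedances occur
        x = np.concatenate([np.linspace(0, 1, 15), np.linspace(0, 1, 15)])
        y = np.concatenate([np.linspace(0, 1, 15), -np.linspace(0, 1, 15)])
        ds = ExpressionDataset(
            ["a", "b"], [f"s{i}" for i in range(30)],
            np.array(["A"] * 15 + ["B"] * 15), np.vstack([x, y]),
        )
        mask = np.zeros_like(ds.missing_mask)
        cfg = PermutationConfig(B_max=400, adaptive=True, h_exceedances=10, seed=3)
        res = adaptive_permutation_test(ds, mask, ("a", "b"), "pearson", cfg)
        assert res.n_permutations == 400
        assert res.p == pytest.approx(1 / 401, abs=0.02)

    def test_determinism(self):
        ds, mask = _perm_dataset(8, seed=2, r=0.3)
        cfg = PermutationConfig(B_max=2000, adaptive=True, seed=9)
        a = adaptive_permutation_test(ds, mask, ("a", "b"), "pearson", cfg)
        b = adaptive_permutation_test(ds, mask, ("a", "b"), "pearson", cfg)
        assert (a.p, a.n_permutations) == (b.p, b.n_permutations)


class TestPairSelection:
    def _records(self):
        return [
            DapRecord("g1", "g2", p_class1=0.001, p_class2=0.5, p_diff=0.01),
            DapRecord("g1", "g3", p_class1=0.2, p_class2=0.3, p_diff=0.20),
            DapRecord("g2", "g3", p_class1=0.9, p_class2=0.04, p_diff=0.60),
        ]

    def test_all_mode(self):
        sel = select_pairs_for_permutation(self._records(), PairSelectionConfig("all"))
        assert len(sel) == 3

    def test_single_class_boundary_alpha_one(self):
        cfg = PairSelectionConfig("single_class_significant", alpha_screen=1.0)
        assert len(select_pairs_for_permutation(self._records(), cfg)) == 3

    def test_single_class_screen(self):
        cfg = PairSelectionConfig("single_class_significant", alpha_screen=0.05)
        sel = select_pairs_for_permutation(self._records(), cfg)
        assert set(sel.pairs) == {("g1", "g2"), ("g2", "g3")}

    def test_difference_prescreen_and_empty_boundary(self):
        cfg = PairSelectionConfig("difference_prescreen", alpha_screen=0.05)
        assert select_pairs_for_permutation(self._records(), cfg).pairs == [("g1", "g2")]
        cfg0 = PairSelectionConfig("difference_prescreen", alpha_screen=0.0)
        assert select_pairs_for_permutation(self._records(), cfg0).pairs == []

    def test_user_list_intersection(self):
        wanted = GenePairList([("g1", "g3"), ("g8", "g9")])
        cfg = PairSelectionConfig("user_list", user_pairs=wanted)
        assert select_pairs_for_permutation(self._records(), cfg).pairs == [("g1", "g3")]
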