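import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dapnet import kendall, mutual_information, pairwise_associations, pearson, spearman
from dapnet.association import all_pairs

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


@pytest.mark.parametrize(
    "func,x,y,expected",
    [
        (pearson, [1, 2, 3], [2, 4, 6], 1.0),
        (pearson, [1, 2, 3], [6, 4, 2], -1.0),
        (pearson, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # sum dxdy=4, sum dx2=sum dy2=5
        (spearman, [1, 2, 3], [1, 4, 9], 1.0),
        (spearman, [1, 2, 3], [9, 4, 1], -1.0),
        (spearman, [1, 1, 2], [1, 2, 3], 0.8660254037844387),  # midranks [1.5,1.5,3]
        (kendall, [1, 2, 3], [1, 2, 3], 1.0),
        (kendall, [1, 2, 3], [3, 2, 1], -1.0),
        (kendall, [1, 2, 3, 4], [1, 3, 2, 4], 4 / 6),  # 5 concordant, 1 discordant
    ],
)
def test_correlation_hand_values(func, x, y, expected):
    est = func(np.array(x, float), np.array(y, float))
    assert est.value == pytest.approx(expected, abs=1e-12)
    assert est.n_eff == len(x)


def test_zero_variance_is_undefined():
    est = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not est.defined and math.isnan(est.value)


def test_pairwise_complete_entries_drive_n_eff():
    x = np.array([1, 2, np.nan, 4, 5.0])
    y = np.array([2, 4, 6, np.nan, 10.0])
    est = pearson(x, y)
    assert est.n_eff == 3
    assert est.value == pytest.approx(1.0)


class TestMutualInformation:
    def test_diagonal_joint_closed_form(self):
        x = np.arange(100, dtype=float)
        est = mutual_information(x, x, n_bins=2)
        assert est.value == pytest.approx(math.log(2), abs=1e-12)
        assert est.metric == "mi"

    def test_independent_large_n_small_nonnegative(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        est = mutual_information(x, y)
        assert 0 <= est.value < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=64), rng.normal(size=64)
        assert mutual_information(x, y).value == pytest.approx(
            mutual_information(y, x).value, abs=1e-12
        )

    def test_too_few_samples_undefined(self):
        est = mutual_information([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_bins=2)
        assert not est.defined

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=128)
        y = x + rng.normal(size=128)
        base = mutual_information(x, y).value
        assert mutual_information(np.exp(x), y**3).value == pytest.approx(base, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.tuples(finite_floats, finite_floats), min_size=3, max_size=8).filter(
        lambda pts: len({p[0] for p in pts}) > 1 and len({p[1] for p in pts}) > 1
    )
)
def test_kendall_matches_brute_force_pair_count(pts):
    """tau-b agrees with exhaustive concordant/discordant enumeration."""
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    if denom == 0:
        return
    assert kendall(x, y).value == pytest.approx((conc - disc) / denom, abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.tuples(finite_floats, finite_floats), min_size=3, max_size=20).filter(
        lambda pts: len({p[0] for p in pts}) > 1 and len({p[1] for p in pts}) > 1
    )
)
def test_spearman_equals_pearson_on_midranks(pts):
    from scipy.stats import rankdata

    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    expected = pearson(rankdata(x), rankdata(y)).value
    got = spearman(x, y).value
    assert (math.isnan(got) and math.isnan(expected)) or got == pytest.approx(expected, abs=1e-9)


def test_pearson_affine_and_rank_monotone_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    y = 0.6 * x + rng.normal(size=40)
    assert pearson(3 * x + 2, y).value == pytest.approx(pearson(x, y).value, abs=1e-12)
    assert spearman(np.exp(x), y).value == pytest.approx(spearman(x, y).value, abs=1e-12)
    assert kendall(x**3, y).value == pytest.approx(kendall(x, y).value, abs=1e-12)


class TestPairwiseAssociations:
    def test_all_pairs_cardinality(self, dataset_factory):
        rng = np.random.default_rng(2)
        ds = dataset_factory(rng.normal(8, 1, (4, 12)), ["A"] * 6 + ["B"] * 6)
        mask = np.zeros_like(ds.missing_mask)
        results, dropped = pairwise_associations(ds, mask, None, "pearson", min_n=4)
        assert len(results) == 6 and not dropped
        assert len(all_pairs(ds)) == 6

    def test_min_n_exclusion_counted(self, dataset_factory):
        rng = np.random.default_rng(2)
        vals = rng.normal(8, 1, (3, 10))
        vals[0, 5:8] = np.nan  # g0 has only 2 complete class-B samples
        ds = dataset_factory(vals, ["A"] * 5 + ["B"] * 5)
        mask = np.zeros_like(ds.missing_mask)
        results, dropped = pairwise_associations(ds, mask, None, "pearson", min_n=4)
        assert ("g0", "g1") in dropped and ("g0", "g2") in dropped
        assert set(results) == {("g1", "g2")}

    def test_gene_order_within_pair_is_irrelevant(self, toy_dataset):
        mask = np.zeros_like(toy_dataset.missing_mask)
        res, _ = pairwise_associations(toy_dataset, mask, None, "spearman", 4)
        for (g1, g2), (e1, e2) in res.items():
            assert g1 < g2
            from dapnet.association import estimate

            i, j = toy_dataset.gene_index(g1), toy_dataset.gene_index(g2)
            cols = toy_dataset.class_sample_indices("A")
            swapped = estimate("spearman", toy_dataset.values[j, cols], toy_dataset.values[i, cols])
            assert swapped.value == pytest.approx(e1.value, abs=1e-12)
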