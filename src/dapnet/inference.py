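"""Statistical tests for differential association.

One-sample Fisher Z-test (H0: rho = 0 within one class), two-sample Fisher
Z-test (H0: rho1 = rho2 between classes, with metric-specific asymptotic
standard errors), and label-permutation tests of the association difference
(fixed-B, exhaustive at small n, and adaptive sequential stopping).

The two-sample standard errors follow the classical large-sample variances of
the Fisher-transformed coefficients: 1/(n-3) for Pearson, 1.06/(n-3) for
Spearman and 0.437/(n-4) for Kendall tau (Fieller–Hartley–Pearson constants).
Mutual information has no analytic test; differences in MI are assessed by
permutation only.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from . import association
from .io import ExpressionDataset, GenePairList, canonical_pair
from .preprocess import pair_complete_columns

_CLAMP_EPS = 1e-7

#: (numerator of the variance of atanh(r), degrees subtracted from n)
_Z_VARIANCE = {"pearson": (1.0, 3), "spearman": (1.06, 3), "kendall": (0.437, 4)}


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    n_permutations: int | None = None


@dataclass
class PermutationConfig:
    """Permutation-test settings.

    B_max: permutation budget per pair (>= 100).
    adaptive: stop a pair early once ``h_exceedances`` permuted statistics at
        least as extreme as the observed one have been seen (sequential
        Besag–Clifford-style rule); cheap for clearly null pairs.
    h_exceedances: stopping count for the adaptive rule (>= 5).
    seed: base seed; each pair derives an independent stream from it.
    exhaustive: enumerate all label assignments instead of sampling. With
        None (default) enumeration is used automatically whenever the number
        of distinct assignments C(n, n1) <= B_max and the test is not
        adaptive, making small-n p-values exact.
    """

    B_max: int = 10_000
    adaptive: bool = False
    h_exceedances: int = 10
    seed: int = 0
    exhaustive: bool | None = None

    def __post_init__(self) -> None:
        if self.B_max < 100:
            raise ValueError("B_max must be >= 100")
        if self.h_exceedances < 5:
            raise ValueError("h_exceedances must be >= 5")
        if self.h_exceedances >= self.B_max:
            raise ValueError("h_exceedances must be < B_max")


@dataclass
class PairSelectionConfig:
    """Which pairs enter the (expensive) permutation phase.

    mode 'all': every pair that passed filtering; 'single_class_significant':
    pairs with a one-sample p below ``alpha_screen`` in at least one class;
    'difference_prescreen': pairs with a two-sample Z-test p below
    ``alpha_screen``; 'user_list': an uploaded pair list intersected with the
    tested pairs.
    """

    mode: str = "all"
    alpha_screen: float = 0.05
    user_pairs: GenePairList | None = None

    MODES = ("all", "single_class_significant", "difference_prescreen", "user_list")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}; choose from {self.MODES}")
        if self.mode in ("single_class_significant", "difference_prescreen"):
            if not (0 <= self.alpha_screen <= 1):
                raise ValueError("alpha_screen must be in [0, 1]")
        if self.mode == "user_list" and self.user_pairs is None:
            raise ValueError("mode 'user_list' requires user_pairs")


def fisher_z_transform(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r) = ½·ln((1+r)/(1−r)).

    |r| within 1e-7 of 1 is clamped (with a warning) so the transform stays
    finite; the nonlinearity inflates z for strong correlations relative to
    moderate ones, which is why asymmetric correlation differences are easier
    to detect than symmetric ones.
    """
    if abs(r) >= 1 - _CLAMP_EPS:
        warnings.warn(f"|r|={abs(r):.9f} clamped to {1 - _CLAMP_EPS} before atanh")
        r = math.copysign(1 - _CLAMP_EPS, r)
    return math.atanh(r)


def _two_sided_normal_p(z):
    return 2.0 * special.ndtr(-np.abs(z))


def one_sample_fisher_z(est: association.AssociationEstimate) -> TestResult | None:
    """Test H0: rho = 0 within one class; Pearson only, needs n_eff >= 4.

    Returns None (reported as "NA") when undefined.
    """
    if est.metric != "pearson":
        raise ValueError("one-sample Fisher Z-test applies to Pearson correlations only")
    if est.n_eff < 4 or not est.defined:
        return None
    z = fisher_z_transform(est.value) * math.sqrt(est.n_eff - 3)
    return TestResult(z, float(_two_sided_normal_p(z)), "one-sample Fisher Z")


def two_sample_fisher_z_arrays(r1, r2, n1, n2, metric: str):
    """Vectorized two-sample Fisher Z-test. Returns (Z, p) arrays."""
    if metric not in _Z_VARIANCE:
        raise ValueError(
            f"no analytic two-sample test for metric {metric!r}; use the permutation test"
        )
    c, d = _Z_VARIANCE[metric]
    r1 = np.clip(np.asarray(r1, dtype=float), -1 + _CLAMP_EPS, 1 - _CLAMP_EPS)
    r2 = np.clip(np.asarray(r2, dtype=float), -1 + _CLAMP_EPS, 1 - _CLAMP_EPS)
    se = np.sqrt(c / (np.asarray(n1) - d) + c / (np.asarray(n2) - d))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    return z, _two_sided_normal_p(z)


def two_sample_fisher_z(
    est1: association.AssociationEstimate, est2: association.AssociationEstimate
) -> TestResult | None:
    """Test H0: rho1 = rho2 across classes via the Fisher Z difference.

    Needs n_eff >= 4 in both classes (>= 5 for Kendall). Returns None when
    undefined; raises for mutual information (no analytic test exists).
    """
    if est1.metric != est2.metric:
        raise ValueError("estimates use different metrics")
    metric = est1.metric
    if metric == "mi":
        raise ValueError("no analytic test for mutual information; use the permutation test")
    _, d = _Z_VARIANCE[metric]
    if min(est1.n_eff, est2.n_eff) < d + 1 or not (est1.defined and est2.defined):
        return None
    z, p = two_sample_fisher_z_arrays(est1.value, est2.value, est1.n_eff, est2.n_eff, metric)
    return TestResult(float(z), float(p), f"two-sample Fisher Z ({metric})")


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _pair_arrays(dataset: ExpressionDataset, mask, pair):
    """Pooled complete values for a pair plus the class-1 membership vector."""
    i, j = dataset.gene_index(pair[0]), dataset.gene_index(pair[1])
    ok = pair_complete_columns(dataset, mask, i, j)
    c1 = dataset.classes[0]
    labels1 = (dataset.class_labels == c1) & ok
    cols = np.flatnonzero(ok)
    return dataset.values[i, cols], dataset.values[j, cols], labels1[cols]


def _diff_stat(metric, x, y, in1):
    e1 = association.estimate(metric, x[in1], y[in1])
    e2 = association.estimate(metric, x[~in1], y[~in1])
    if not (e1.defined and e2.defined):
        return None
    return e1.value - e2.value


def _pearson_diff_masks(x, y, masks):
    """Observed-minus-complement Pearson difference for many subset masks.

    ``masks`` is (B, n) boolean with a constant row sum n1. Rows where either
    subset degenerates (zero variance) return NaN.
    """
    masks = np.asarray(masks, dtype=float)
    n = x.size
    n1 = masks[0].sum()
    n2 = n - n1

    def _corr(m, k):
        sx = m @ x
        sy = m @ y
        sxx = m @ (x * x)
        syy = m @ (y * y)
        sxy = m @ (x * y)
        num = k * sxy - sx * sy
        den = (k * sxx - sx * sx) * (k * syy - sy * sy)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.sqrt(np.maximum(den, 1e-300)), np.nan)

    return _corr(masks, n1) - _corr(1.0 - masks, n2)


def _exhaustive_masks(n, n1):
    combos = list(itertools.combinations(range(n), n1))
    masks = np.zeros((len(combos), n), dtype=bool)
    for b, idx in enumerate(combos):
        masks[b, list(idx)] = True
    return masks


def _random_masks(rng, B, n, n1):
    u = rng.random((B, n))
    idx = np.argpartition(u, n1 - 1, axis=1)[:, :n1]
    masks = np.zeros((B, n), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


_DEGENERATE_RETRIES = 10


def _perm_distribution(metric, x, y, masks, rng, redraw: bool):
    """|d| for each permutation mask; degenerate draws are redrawn (bounded)
    then conservatively set to +inf (counted as exceedances)."""
    n, n1 = x.size, int(masks[0].sum())
    if metric == "pearson":
        d = _pearson_diff_masks(x, y, masks)
    else:
        d = np.empty(len(masks))
        for b, m in enumerate(masks):
            v = _diff_stat(metric, x, y, m)
            d[b] = np.nan if v is None else v
    bad = np.flatnonzero(~np.isfinite(d))
    for b in bad:
        ok = False
        if redraw:
            for _ in range(_DEGENERATE_RETRIES):
                m = _random_masks(rng, 1, n, n1)[0]
                v = _diff_stat(metric, x, y, m)
                if v is not None and math.isfinite(v):
                    d[b] = v
                    ok = True
                    break
        if not ok:
            d[b] = np.inf  # conservative: counts as an exceedance
    return np.abs(d)


def permutation_test_difference(
    dataset: ExpressionDataset,
    mask,
    pair,
    metric: str,
    config: PermutationConfig,
) -> TestResult | None:
    """Label-permutation test of d = assoc_class1 − assoc_class2.

    Class labels are reassigned to samples (each sample's two gene values
    travel together) preserving class sizes, so within-sample gene–gene
    dependence is kept and only "no class difference in association" is
    broken. Small problems are enumerated exhaustively (exact p); otherwise
    the add-one estimator p = (1 + #{|d_perm| >= |d_obs|}) / (1 + B) is used,
    which never returns 0. Deterministic given ``config.seed``.
    """
    if config.adaptive:
        return adaptive_permutation_test(dataset, mask, pair, metric, config)
    x, y, in1 = _pair_arrays(dataset, mask, pair)
    d_obs = _diff_stat(metric, x, y, in1)
    if d_obs is None:
        return None
    n, n1 = x.size, int(in1.sum())
    rng = _pair_rng(config.seed, pair)
    n_total = math.comb(n, n1)
    exhaustive = config.exhaustive if config.exhaustive is not None else n_total <= config.B_max
    if exhaustive:
        masks = _exhaustive_masks(n, n1)
        absd = _perm_distribution(metric, x, y, masks, rng, redraw=False)
        exceed = int(np.sum(absd >= abs(d_obs) - 1e-12))
        p = exceed / n_total
        return TestResult(d_obs, p, f"permutation ({metric}, exhaustive)", n_total)
    masks = _random_masks(rng, config.B_max, n, n1)
    absd = _perm_distribution(metric, x, y, masks, rng, redraw=True)
    exceed = int(np.sum(absd >= abs(d_obs) - 1e-12))
    p = (1 + exceed) / (1 + config.B_max)
    return TestResult(d_obs, p, f"permutation ({metric})", config.B_max)


def adaptive_permutation_test(
    dataset: ExpressionDataset,
    mask,
    pair,
    metric: str,
    config: PermutationConfig,
) -> TestResult | None:
    """Sequential permutation test: stop at the h-th exceedance.

    Draw permutations until ``h_exceedances`` permuted statistics at least as
    extreme as the observed one have been seen — then p = h / (draws used) —
    or until B_max is exhausted, where the add-one estimator applies. Clearly
    null pairs stop after few draws; extreme pairs run to B_max.
    """
    x, y, in1 = _pair_arrays(dataset, mask, pair)
    d_obs = _diff_stat(metric, x, y, in1)
    if d_obs is None:
        return None
    n, n1 = x.size, int(in1.sum())
    rng = _pair_rng(config.seed, pair)
    h = config.h_exceedances
    exceed = 0
    drawn = 0
    block = 128
    while drawn < config.B_max:
        b = min(block, config.B_max - drawn)
        masks = _random_masks(rng, b, n, n1)
        absd = _perm_distribution(metric, x, y, masks, rng, redraw=True)
        hits = absd >= abs(d_obs) - 1e-12
        cum = exceed + np.cumsum(hits)
        stop = np.flatnonzero(cum >= h)
        if stop.size:
            used = drawn + int(stop[0]) + 1
            return TestResult(d_obs, h / used, f"permutation ({metric}, adaptive)", used)
        exceed = int(cum[-1]) if b else exceed
        drawn += b
    p = (1 + exceed) / (1 + config.B_max)
    return TestResult(d_obs, p, f"permutation ({metric}, adaptive)", config.B_max)


def _pair_rng(seed: int, pair) -> np.random.Generator:
    # independent, order-invariant stream per pair (crc32: stable across runs)
    g1, g2 = canonical_pair(*pair)
    digest = zlib.crc32(f"{g1}\t{g2}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest]))


def select_pairs_for_permutation(records, config: PairSelectionConfig) -> GenePairList:
    """Choose the pair subset that enters the permutation phase.

    ``records`` must already carry the Z-phase results for the screening
    modes. An empty selection returns an empty list (caller warns and skips
    the permutation phase).
    """
    tested = [r.pair for r in records]
    if config.mode == "all":
        return GenePairList(list(tested))
    if config.mode == "user_list":
        wanted = set(config.user_pairs.pairs)
        return GenePairList([p for p in tested if canonical_pair(*p) in wanted])
    if config.mode == "single_class_significant":
        keep = [
            r.pair for r in records
            if (r.p_class1 is not None and r.p_class1 < config.alpha_screen)
            or (r.p_class2 is not None and r.p_class2 < config.alpha_screen)
        ]
        return GenePairList(keep)
    # difference_prescreen
    keep = [r.pair for r in records if r.p_diff is not None and r.p_diff < config.alpha_screen]
    return GenePairList(keep)


def run_dapfinder(
    dataset: ExpressionDataset,
    filter_config=None,
    metric: str = "pearson",
    permutation_config: PermutationConfig | None = None,
    selection_config: PairSelectionConfig | None = None,
    adjustment: str = "bh",
    pairs: GenePairList | None = None,
    output_dir=None,
    top10: bool = True,
):
    """Full DAP pipeline; thin wrapper over :class:`dapnet.DAPFinder`.

    Returns ``(records, report)``; when ``output_dir`` is given, also writes
    the result table, edge list and HTML report there.
    """
    from .estimator import DAPFinder  # local import: avoid cycle

    est = DAPFinder(
        metric=metric,
        filter_config=filter_config,
        permutation_config=permutation_config,
        selection_config=selection_config,
        adjust_method=adjustment,
        pairs=pairs,
        top10=top10,
    )
    est.fit(dataset)
    if output_dir is not None:
        est.write_outputs(output_dir)
    return est.records_, est.report_
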