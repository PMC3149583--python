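"""Pairwise gene–gene association metrics.

Four metrics are supported: Pearson product-moment correlation, Spearman rank
correlation (average ranks for ties), Kendall tau-b (tie corrected) and a
plug-in mutual-information estimate on equal-frequency (quantile) bins,
reported in nats. All metrics operate on the pairwise-complete entries of the
two input vectors: positions where either value is non-finite are dropped
before estimation, and the count actually used is returned as ``n_eff``.

An undefined estimate (zero variance, too few observations, all ties) is
returned as NaN rather than raised, so callers can flag and exclude the pair
downstream.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionDataset, GenePairList, canonical_pair
from .preprocess import pair_complete_columns

METRICS = ("pearson", "spearman", "kendall", "mi")


@dataclass
class AssociationEstimate:
    metric: str
    value: float  # correlation in [-1, 1]; MI >= 0 in nats; NaN if undefined
    n_eff: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


def _complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson(x, y) -> AssociationEstimate:
    x, y = _complete(x, y)
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationEstimate("pearson", float("nan"), n)
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return AssociationEstimate("pearson", max(-1.0, min(1.0, r)), n)


def spearman(x, y) -> AssociationEstimate:
    """Pearson correlation of midranks (ties receive average ranks)."""
    x, y = _complete(x, y)
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationEstimate("spearman", float("nan"), n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    est = pearson(rx, ry)
    return AssociationEstimate("spearman", est.value, n)


def kendall(x, y) -> AssociationEstimate:
    """Kendall's tau-b, tie corrected."""
    x, y = _complete(x, y)
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationEstimate("kendall", float("nan"), n)
    tau = stats.kendalltau(x, y, variant="b").statistic
    return AssociationEstimate("kendall", float(tau), n)


def mutual_information(x, y, n_bins: int | str = "auto") -> AssociationEstimate:
    """Plug-in mutual information (nats) on a quantile-binned joint histogram.

    Each axis is cut into B equal-frequency bins; when ``n_bins='auto'``,
    B = max(2, floor(log2(n))). Quantile binning makes the estimate invariant
    under strictly monotone transforms of either margin. Requires n >= 2·B.
    """
    x, y = _complete(x, y)
    n = x.size
    if n_bins == "auto":
        b = max(2, int(math.floor(math.log2(n)))) if n >= 2 else 2
    else:
        b = int(n_bins)
        if b < 2:
            raise ValueError("n_bins must be >= 2")
    if n < 2 * b:
        return AssociationEstimate("mi", float("nan"), n)
    ix = _quantile_bins(x, b)
    iy = _quantile_bins(y, b)
    joint = np.zeros((ix.max() + 1, iy.max() + 1))
    np.add.at(joint, (ix, iy), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return AssociationEstimate("mi", max(0.0, mi), n)


def _quantile_bins(v: np.ndarray, b: int) -> np.ndarray:
    # interior quantile edges; duplicates (heavy ties) collapse to fewer bins
    edges = np.unique(np.quantile(v, np.linspace(0, 1, b + 1)[1:-1]))
    return np.searchsorted(edges, v, side="right")


_METRIC_FUNCS = {
    "pearson": pearson,
    "spearman": spearman,
    "kendall": kendall,
    "mi": mutual_information,
}


def estimate(metric: str, x, y) -> AssociationEstimate:
    """Dispatch to the named association metric."""
    try:
        return _METRIC_FUNCS[metric](x, y)
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}") from None


def all_pairs(dataset: ExpressionDataset) -> GenePairList:
    """Every unordered gene pair, in canonical order."""
    return GenePairList(
        [canonical_pair(a, b) for a, b in itertools.combinations(dataset.gene_ids, 2)]
    )


def pairwise_associations(
    dataset: ExpressionDataset,
    mask: np.ndarray,
    pairs: GenePairList | None,
    metric: str,
    min_n: int = 4,
) -> tuple[dict, list]:
    """Per-class association estimates for each pair on pairwise-complete data.

    Returns ``(results, dropped)`` where ``results`` maps canonical pair ->
    (estimate_class1, estimate_class2) and ``dropped`` lists pairs excluded
    because n_eff < min_n in either class (or the estimate was undefined).
    """
    dataset.require_two_classes()
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if pairs is None:
        pairs = all_pairs(dataset)
    c1, c2 = dataset.classes
    idx1 = dataset.class_sample_indices(c1)
    idx2 = dataset.class_sample_indices(c2)
    values = np.where(mask | dataset.missing_mask, np.nan, dataset.values)

    results: dict[tuple[str, str], tuple[AssociationEstimate, AssociationEstimate]] = {}
    dropped: list[tuple[str, str]] = []
    for g1, g2 in pairs:
        i, j = dataset.gene_index(g1), dataset.gene_index(g2)
        est1 = estimate(metric, values[i, idx1], values[j, idx1])
        est2 = estimate(metric, values[i, idx2], values[j, idx2])
        if est1.n_eff < min_n or est2.n_eff < min_n or not (est1.defined and est2.defined):
            dropped.append(canonical_pair(g1, g2))
            continue
        results[canonical_pair(g1, g2)] = (est1, est2)
    if not results and not dropped:
        raise ValueError("no pairs to evaluate")
    if not results:
        raise ValueError("all pairs excluded by the minimum-sample-size criterion")
    return results, dropped
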