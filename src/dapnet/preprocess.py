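"""Gene-level pre-filtering and univariate outlier flagging.

Filtering happens before association estimation: genes may be dropped by a
coefficient-of-variation threshold, and individual expression values may be
flagged as outliers by a standard-deviation or interquartile-range rule,
applied per class (default) or pooled across classes. Flagging is single
pass: the rule is applied once to the observed values, never iterated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset

logger = logging.getLogger("dapnet")


@dataclass
class FilterConfig:
    """Pre-filtering settings.

    cv_min: drop genes whose CV (sample SD / |mean|, non-missing values)
        falls below this; None disables.
    min_n_per_class: minimum pairwise-complete sample count per class for a
        pair to be tested. Must be >= 4 (Fisher Z needs n-3 > 0, Kendall's
        approximate test n-4 > 0).
    outlier_method: 'none', 'sd' (mean ± k·SD) or 'iqr' (quartiles ± k·IQR).
    outlier_k: rule multiplier; defaults to 3.0 for 'sd', 1.5 for 'iqr'.
    outlier_scope: 'per_class' (default; associations are estimated within
        class, so class mean shifts should not look like outliers) or 'pooled'.
    """

    cv_min: float | None = None
    min_n_per_class: int = 4
    outlier_method: str = "none"
    outlier_k: float | None = None
    outlier_scope: str = "per_class"

    def __post_init__(self) -> None:
        if self.min_n_per_class is None:
            self.min_n_per_class = 4
        if self.min_n_per_class < 4:
            raise ValueError("min_n_per_class must be >= 4")
        if self.outlier_method not in ("none", "sd", "iqr"):
            raise ValueError(f"unknown outlier_method {self.outlier_method!r}")
        if self.outlier_scope not in ("per_class", "pooled"):
            raise ValueError(f"unknown outlier_scope {self.outlier_scope!r}")
        if self.outlier_k is None:
            self.outlier_k = {"sd": 3.0, "iqr": 1.5, "none": 0.0}[self.outlier_method]
        elif self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")

    def resolve_mask(self, dataset: ExpressionDataset) -> np.ndarray:
        if self.outlier_method == "sd":
            return flag_outliers_sd(dataset, self.outlier_k, self.outlier_scope)
        if self.outlier_method == "iqr":
            return flag_outliers_iqr(dataset, self.outlier_k, self.outlier_scope)
        return np.zeros_like(dataset.missing_mask)


def cv_filter(dataset: ExpressionDataset, cv_min: float) -> set[str]:
    """Return the gene IDs whose coefficient of variation is >= ``cv_min``.

    CV = sample (n-1) standard deviation / |mean| over non-missing values.
    Genes with mean exactly 0 have undefined CV and are removed with a warning.
    """
    if cv_min < 0:
        raise ValueError("cv_min must be nonnegative")
    retained: set[str] = set()
    for i, gid in enumerate(dataset.gene_ids):
        vals = dataset.values[i, ~dataset.missing_mask[i]]
        if vals.size == 0:
            continue
        mean = vals.mean()
        if mean == 0:
            logger.warning("gene %s removed: CV undefined (mean 0)", gid)
            continue
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        if sd / abs(mean) >= cv_min:
            retained.add(gid)
    return retained


def _scope_groups(dataset: ExpressionDataset, scope: str) -> list[np.ndarray]:
    if scope == "pooled":
        return [np.arange(dataset.n_samples)]
    return [dataset.class_sample_indices(c) for c in dataset.classes]


def flag_outliers_sd(dataset: ExpressionDataset, k: float, scope: str = "per_class") -> np.ndarray:
    """Flag values outside mean ± k·(sample SD), per gene per scope group.

    Groups with fewer than 3 non-missing values are never flagged (the SD
    estimate is too unstable to call outliers).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mask = np.zeros_like(dataset.missing_mask)
    for cols in _scope_groups(dataset, scope):
        sub = dataset.values[:, cols]
        obs = ~dataset.missing_mask[:, cols]
        for i in range(dataset.n_genes):
            vals = sub[i, obs[i]]
            if vals.size < 3:
                continue
            mean, sd = vals.mean(), vals.std(ddof=1)
            out = obs[i] & ((sub[i] < mean - k * sd) | (sub[i] > mean + k * sd))
            mask[i, cols[out]] = True
    return mask


def flag_outliers_iqr(dataset: ExpressionDataset, k: float, scope: str = "per_class") -> np.ndarray:
    """Flag values outside [Q1 − k·IQR, Q3 + k·IQR], per gene per scope group.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention). Groups with fewer than 4 non-missing values are
    never flagged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mask = np.zeros_like(dataset.missing_mask)
    for cols in _scope_groups(dataset, scope):
        sub = dataset.values[:, cols]
        obs = ~dataset.missing_mask[:, cols]
        for i in range(dataset.n_genes):
            vals = sub[i, obs[i]]
            if vals.size < 4:
                continue
            q1, q3 = np.percentile(vals, [25, 75], method="linear")
            iqr = q3 - q1
            out = obs[i] & ((sub[i] < q1 - k * iqr) | (sub[i] > q3 + k * iqr))
            mask[i, cols[out]] = True
    return mask


def effective_pair_n(
    dataset: ExpressionDataset,
    mask: np.ndarray,
    g1: str,
    g2: str,
    class_label,
) -> int:
    """Pairwise-complete sample count for a gene pair within one class.

    Counts samples where BOTH genes are non-missing and not outlier-flagged.
    """
    i, j = dataset.gene_index(g1), dataset.gene_index(g2)
    cols = dataset.class_sample_indices(class_label)
    ok = ~(dataset.missing_mask[i, cols] | mask[i, cols]
           | dataset.missing_mask[j, cols] | mask[j, cols])
    return int(ok.sum())


def pair_complete_columns(
    dataset: ExpressionDataset, mask: np.ndarray, i: int, j: int
) -> np.ndarray:
    """Boolean sample vector: both genes observed and unflagged (all classes)."""
    return ~(dataset.missing_mask[i] | mask[i] | dataset.missing_mask[j] | mask[j])
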