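"""Multiple-testing adjustment of p-value families.

Each test family (one-sample per class, two-sample Z, permutation) is
adjusted separately. Benjamini–Hochberg FDR and the Bonferroni/Holm/Hochberg
FWER variants are delegated to statsmodels; Storey q-values are implemented
here (pi0 estimated by smoothing the tail proportion over a lambda grid).
All adjustments preserve the rank order of the raw p-values and stay in
[0, 1]; every adjusted value is >= its raw value (for q-values, once pi0 has
been folded in, q >= pi0 * p).
"""

from __future__ import annotations

import warnings

import numpy as np
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = ("none", "bh", "qvalue", "bonferroni", "holm", "hochberg")


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return p


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = _check_p(p)
    return multipletests(p, method="fdr_bh")[1]


_FWER_METHODS = {"bonferroni": "bonferroni", "holm": "holm", "hochberg": "simes-hochberg"}


def adjust_fwer(p, variant: str = "hochberg") -> np.ndarray:
    """FWER-adjusted p-values: 'bonferroni', 'holm' (step-down) or 'hochberg'
    (step-up, the default)."""
    p = _check_p(p)
    try:
        method = _FWER_METHODS[variant]
    except KeyError:
        raise ValueError(f"unknown FWER variant {variant!r}; choose from {list(_FWER_METHODS)}")
    return multipletests(p, method=method)[1]


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


def estimate_pi0(p, lambda_grid=None) -> float:
    """Storey's pi0 (proportion of true nulls): smooth #{p > lambda} /
    ((1 - lambda) m) over the grid and evaluate at the largest lambda.

    The smoother is a cubic least-squares fit over the grid. Estimates above
    1 are clamped to 1 with a warning; a misbehaving fit falls back to 1.
    """
    p = _check_p(p)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if np.any((grid < 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie in [0, 1)")
    m = p.size
    pi0_raw = np.array([np.mean(p > lam) / (1 - lam) for lam in grid])
    if grid.size < 4:
        pi0 = float(pi0_raw[-1])
    else:
        try:
            coef = np.polyfit(grid, pi0_raw, deg=3)
            pi0 = float(np.polyval(coef, grid.max()))
        except Exception:
            pi0 = 1.0
    if not np.isfinite(pi0):
        pi0 = 1.0
    if pi0 > 1:
        warnings.warn(f"pi0 estimate {pi0:.3f} > 1; clamped to 1")
        pi0 = 1.0
    return max(pi0, 1.0 / m)


def qvalues(p, lambda_grid=None) -> np.ndarray:
    """Storey q-values: q(i) = min over j >= i of pi0 * p(j) * m / j, i.e.
    pi0 times the BH-adjusted value, clamped to [0, 1].

    Fewer than 10 p-values make pi0 estimation unreliable (warned).
    """
    p = _check_p(p)
    if p.size < 10:
        warnings.warn("q-value estimation is unreliable for fewer than 10 p-values")
    pi0 = estimate_pi0(p, lambda_grid)
    return np.clip(pi0 * adjust_bh(p), 0.0, 1.0)


def adjust(p, method: str) -> np.ndarray:
    """Dispatch by method name ('none' returns the input unchanged)."""
    if method == "none":
        return _check_p(p).copy()
    if method == "bh":
        return adjust_bh(p)
    if method == "qvalue":
        return qvalues(p)
    if method in _FWER_METHODS:
        return adjust_fwer(p, method)
    raise ValueError(f"unknown adjustment {method!r}; choose from {ADJUST_METHODS}")
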