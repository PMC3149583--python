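"""Two-class expression simulation with known pair correlations, plus the
ROC/AUC and p-value-concordance machinery used to evaluate DAP detection.

The generator emulates a two-class microarray experiment: genes come in G/2
disjoint pairs, each pair drawn from a bivariate normal (common mean and SD
for every gene) with a known correlation per class. A configurable fraction
of pairs are true DAPs (correlation r_i in class 1, r_j in class 2); the rest
are null pairs with the same correlation (default 0) in both classes. Pairs
are mutually independent. Defaults — log2-like mean 8, SD 1, half the pairs
DAPs, 40 genes per chip, 250 runs — reflect typical small two-channel
microarray evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import inference
from .io import ExpressionDataset

CLASS1, CLASS2 = "class1", "class2"


@dataclass
class SimulationScenario:
    """Generator parameters for one evaluation condition.

    n_per_class: chips (samples) per class, >= 4.
    genes_per_chip: even G; genes are organized as G/2 disjoint pairs.
    n_runs: independent datasets generated and pooled.
    r_class1 / r_class2: target correlation of a DAP pair in each class
        (|r| < 1); delta = r_class1 - r_class2 is the effect size.
    r_null: correlation of non-DAP pairs, identical in both classes.
    dap_fraction: fraction of pairs that are true DAPs (ceil applied).
    gene_mean / gene_sd: marginal mean and SD of every simulated gene
        (log-scale expression units).
    seed: base seed; run k uses the stream (seed, k).
    """

    n_per_class: int = 10
    genes_per_chip: int = 40
    n_runs: int = 250
    r_class1: float = 0.5
    r_class2: float = -0.5
    r_null: float = 0.0
    dap_fraction: float = 0.5
    gene_mean: float = 8.0
    gene_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 4:
            raise ValueError("n_per_class must be >= 4")
        if self.genes_per_chip % 2 or self.genes_per_chip < 2:
            raise ValueError("genes_per_chip must be a positive even integer")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for r in (self.r_class1, self.r_class2, self.r_null):
            if not abs(r) < 1:
                raise ValueError(f"correlations must satisfy |r| < 1, got {r}")
        if not 0 < self.dap_fraction <= 1:
            raise ValueError("dap_fraction must be in (0, 1]")
        if self.gene_sd <= 0:
            raise ValueError("gene_sd must be positive")

    @property
    def n_pairs(self) -> int:
        return self.genes_per_chip // 2

    @property
    def n_dap_pairs(self) -> int:
        return math.ceil(self.dap_fraction * self.n_pairs)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # p-value cutoffs (predict DAP when p <= t)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ConcordanceResult:
    n_per_class: int
    correlation: float  # Pearson r between Fisher-Z and permutation p-values
    n_pairs: int = 0
    fisher_p: np.ndarray = field(default_factory=lambda: np.array([]))
    perm_p: np.ndarray = field(default_factory=lambda: np.array([]))


def _run_rng(scenario: SimulationScenario, run_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed) & 0x7FFFFFFF, int(run_index)])
    )


def _simulate_xy(rng, n, r_vec, mean, sd):
    """(n, P) twin arrays with per-pair correlation r_vec."""
    p = r_vec.size
    z1 = rng.standard_normal((n, p))
    z2 = rng.standard_normal((n, p))
    x = z1
    y = r_vec * z1 + np.sqrt(1.0 - r_vec**2) * z2
    return mean + sd * x, mean + sd * y


def pair_truth(scenario: SimulationScenario) -> np.ndarray:
    """Boolean DAP indicator per pair: the first ceil(f·G/2) pairs are DAPs."""
    truth = np.zeros(scenario.n_pairs, dtype=bool)
    truth[: scenario.n_dap_pairs] = True
    return truth


def _target_r(scenario: SimulationScenario):
    truth = pair_truth(scenario)
    r1 = np.where(truth, scenario.r_class1, scenario.r_null)
    r2 = np.where(truth, scenario.r_class2, scenario.r_null)
    return truth, r1, r2


def generate_dataset(scenario: SimulationScenario, run_index: int = 0):
    """One simulated two-class dataset; returns (dataset, truth_by_pair).

    ``truth_by_pair`` maps the canonical gene-ID pair to its DAP indicator.
    Gene 2k and gene 2k+1 form pair k.
    """
    rng = _run_rng(scenario, run_index)
    truth, r1, r2 = _target_r(scenario)
    n, mean, sd = scenario.n_per_class, scenario.gene_mean, scenario.gene_sd
    x1, y1 = _simulate_xy(rng, n, r1, mean, sd)
    x2, y2 = _simulate_xy(rng, n, r2, mean, sd)

    g = scenario.genes_per_chip
    values = np.empty((g, 2 * n))
    values[0::2, :n] = x1.T
    values[1::2, :n] = y1.T
    values[0::2, n:] = x2.T
    values[1::2, n:] = y2.T

    width = len(str(g))
    gene_ids = [f"g{k:0{width}d}" for k in range(g)]
    sample_ids = [f"{CLASS1}_s{i}" for i in range(n)] + [f"{CLASS2}_s{i}" for i in range(n)]
    labels = np.array([CLASS1] * n + [CLASS2] * n)
    ds = ExpressionDataset(gene_ids, sample_ids, labels, values)
    truth_by_pair = {
        (gene_ids[2 * k], gene_ids[2 * k + 1]): bool(truth[k]) for k in range(scenario.n_pairs)
    }
    return ds, truth_by_pair


def _pair_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson r of columns (2k, 2k+1) of an (n, G) matrix, vectorized."""
    x = values[:, 0::2]
    y = values[:, 1::2]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    return num / den


def run_scenario(
    scenario: SimulationScenario,
    test: str = "fisher_z",
    permutation_config: inference.PermutationConfig | None = None,
):
    """Two-sample p-value and truth label for every pair in every run.

    Returns ``(p, truth)`` as flat arrays of length n_runs · G/2, pooled over
    runs. ``test`` is 'fisher_z' (analytic) or 'permutation'.
    """
    if test not in ("fisher_z", "permutation"):
        raise ValueError("test must be 'fisher_z' or 'permutation'")
    truth, _, _ = _target_r(scenario)
    n = scenario.n_per_class
    all_p = []
    for run in range(scenario.n_runs):
        ds, _ = generate_dataset(scenario, run)
        if test == "fisher_z":
            v = ds.values.T
            r1 = _pair_correlations(v[:n])
            r2 = _pair_correlations(v[n:])
            _, p = inference.two_sample_fisher_z_arrays(r1, r2, n, n, "pearson")
        else:
            cfg = permutation_config or inference.PermutationConfig(
                B_max=1000, seed=scenario.seed + 7919 * run
            )
            mask = np.zeros_like(ds.missing_mask)
            p = np.array([
                inference.permutation_test_difference(
                    ds, mask, (ds.gene_ids[2 * k], ds.gene_ids[2 * k + 1]), "pearson", cfg
                ).p
                for k in range(scenario.n_pairs)
            ])
        all_p.append(p)
    p = np.concatenate(all_p)
    return p, np.tile(truth, scenario.n_runs)


def compute_roc_auc(p, truth) -> RocCurve:
    """ROC over the p-value sweep (predict DAP when p <= t), trapezoidal AUC.

    Tied p-values enter at the same threshold. Requires both truth classes.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both DAP and null pairs in the truth labels")
    fpr, tpr, thr = _sk_roc_curve(truth.astype(int), -p)
    return RocCurve(thresholds=-thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def scenario_auc(scenario: SimulationScenario, test: str = "fisher_z", **kwargs) -> float:
    """Pooled-ROC AUC for one scenario (convenience wrapper)."""
    p, truth = run_scenario(scenario, test=test, **kwargs)
    return compute_roc_auc(p, truth).auc


def pvalue_concordance(
    scenario: SimulationScenario, B: int = 1000
) -> ConcordanceResult:
    """Correlation between analytic (Fisher Z) and permutation p-values.

    Each pair in each run contributes one (p_fisher, p_perm) point computed on
    the same generated data; the result is their Pearson correlation pooled
    over runs.
    """
    n = scenario.n_per_class
    fisher, perm = [], []
    for run in range(scenario.n_runs):
        ds, _ = generate_dataset(scenario, run)
        v = ds.values.T
        r1 = _pair_correlations(v[:n])
        r2 = _pair_correlations(v[n:])
        _, p_f = inference.two_sample_fisher_z_arrays(r1, r2, n, n, "pearson")
        cfg = inference.PermutationConfig(
            B_max=max(100, B), seed=scenario.seed + 7919 * run, exhaustive=False
        )
        mask = np.zeros_like(ds.missing_mask)
        p_p = [
            inference.permutation_test_difference(
                ds, mask, (ds.gene_ids[2 * k], ds.gene_ids[2 * k + 1]), "pearson", cfg
            ).p
            for k in range(scenario.n_pairs)
        ]
        fisher.append(p_f)
        perm.append(np.asarray(p_p))
    p_f = np.concatenate(fisher)
    p_p = np.concatenate(perm)
    corr = float(np.corrcoef(p_f, p_p)[0, 1])
    return ConcordanceResult(
        n_per_class=n, correlation=corr, n_pairs=p_f.size, fisher_p=p_f, perm_p=p_p
    )
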