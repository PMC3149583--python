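# dapnet

Differential gene coexpression analysis between two phenotypes: find
**Differentially Associated Pairs (DAPs)** — gene pairs whose pairwise
association differs significantly between two sample classes — and export the
results as a coexpression network.

Traditional per-gene tests (t-tests, ANOVA, empirical Bayes) find genes whose
*level* changes between phenotypes but are blind to changes in how genes vary
*together*. A pair of genes can keep identical means in two tumor types yet be
tightly coregulated in one and decoupled in the other; such rewiring of the
coexpression network is invisible to differential-expression analysis. dapnet
tests exactly this: for every gene pair, is the within-class association the
same in both phenotypes?

## The statistics

For genes *i*, *j* and classes 1, 2, the association r is estimated per class
with Pearson, Spearman or Kendall (tau-b) correlation or quantile-binned
mutual information, on pairwise-complete, outlier-filtered values.

- **One-sample Fisher Z-test** (Pearson): H₀: ρ = 0 within one class, using
  z·√(n−3) with z = atanh(r), two-sided normal p-value.
- **Two-sample Fisher Z-test**: H₀: ρ₁ = ρ₂, using
  Z = (atanh(r₁) − atanh(r₂)) / SE with SE² = c/(n₁−d) + c/(n₂−d), where
  (c, d) = (1, 3) for Pearson, (1.06, 3) for Spearman, (0.437, 4) for Kendall
  (Fieller–Hartley–Pearson constants).
- **Permutation test** (any metric, incl. mutual information): sample-to-class
  labels are reshuffled (class sizes preserved, each sample's values travel
  together), the null distribution of d = r₁ − r₂ is built, and
  p = (1 + #{|d*| ≥ |d|}) / (1 + B). Small problems are enumerated
  exhaustively (exact p); an adaptive sequential mode stops a pair early once
  enough null exceedances have been seen.
- **Multiple testing**: Benjamini–Hochberg FDR, Storey q-values, and
  Bonferroni / Holm / Hochberg FWER, applied per test family.

A simulation module generates two-class data with known per-pair correlations
and scores detection with pooled ROC curves, for power analysis and
calibration checks.

## Worked example

```python
import numpy as np
from dapnet import DAPFinder, PermutationConfig

rng = np.random.default_rng(7)
n = 15                                   # samples per phenotype
x = rng.normal(8, 1, 2 * n)
y = np.empty_like(x)
y[:n] = 0.9 * (x[:n] - 8) + np.sqrt(1 - 0.81) * rng.normal(size=n) + 8
y[n:] = rng.normal(8, 1, n)              # coexpressed in class A only
X = np.column_stack([x, y, rng.normal(8, 1, (2 * n, 3))])
labels = np.array(["tumorA"] * n + ["tumorB"] * n)

finder = DAPFinder(permutation_config=PermutationConfig(B_max=2000, seed=0))
finder.fit(X, labels)
print(finder.results_[["gene1_id", "gene2_id", "assoc_class1", "assoc_class2",
                       "delta", "z_diff", "p_diff", "p_diff_adj", "p_perm"]]
      .head(3).round(4).to_string(index=False))
print("significant DAPs (BH-adjusted p < 0.05):", finder.significant_pairs(0.05))
```

prints

```
gene1_id gene2_id  assoc_class1  assoc_class2  delta  z_diff  p_diff  p_diff_adj  p_perm
      g0       g1        0.8867       -0.2549 1.1416  4.0833  0.0000      0.0004  0.0025
      g2       g3        0.1932       -0.2597 0.4529  1.1303  0.2583      0.9523  0.1884
      g3       g4       -0.2836       -0.6098 0.3262  1.0214  0.3071      0.9523  0.1414

significant DAPs (BH-adjusted p < 0.05): [('g0', 'g1')]
```

The planted pair (g0, g1) — r ≈ 0.89 in `tumorA`, r ≈ −0.25 in `tumorB`,
Δr ≈ 1.14 — is the only pair flagged after FDR adjustment: its Fisher Z
statistic 4.08 gives an adjusted p of 4×10⁻⁴, and the label-permutation test
agrees (p ≈ 0.0025). Every other pair is null and lands far from significance.

### Command line

```bash
dapnet dapfinder --input expr.tsv --labels labels.tsv --out results/ \
       --metric pearson --adjust bh --perm 1000 --seed 1
dapnet dapview  --input expr.tsv --labels labels.tsv \
       --gene1 MYT1L --gene2 SOX5 --outlier-mode identify --out pair.pdf
dapnet simulate --n 10 --genes 40 --runs 250 --r1 0.5 --r2 -0.5 \
       --seed 1 --out sim/
```

`dapfinder` writes the comprehensive result table (TSV), a Cytoscape-ready
edge list (source, target, interaction, weight) and an HTML run report;
`dapview` writes a two-class scatter PDF with outliers identified in red,
eliminated, or ignored; `simulate` writes pooled (p, truth) entries, the ROC
curve and an AUC summary.

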