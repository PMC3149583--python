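# Methods

## Model and procedure

dapnet compares pairwise gene–gene association between exactly two phenotype
classes. For each gene pair and class, an association is estimated on the
pairwise-complete, outlier-filtered expression values; the class difference is
then tested analytically (Fisher Z) and/or empirically (label permutation).
The pipeline, in order:

1. **Gene filtering.** Optional coefficient-of-variation filter
   (CV = sample SD / |mean| over non-missing values; genes with mean exactly 0
   have undefined CV and are dropped with a warning) and a minimum
   pairwise-complete sample size per class (default and floor: 4, because the
   Pearson/Spearman Z-tests need n − 3 > 0 and the Kendall test n − 4 > 0).
2. **Outlier flagging.** Univariate, single pass (the rule is applied once to
   the observed values, never iterated on the cleaned data): values outside
   mean ± k·SD (default k = 3) or outside [Q1 − k·IQR, Q3 + k·IQR]
   (default k = 1.5, quartiles by linear interpolation between order
   statistics, the "type 7" convention — IQR flags near the fence depend on
   the convention, so it is fixed and documented). Scope is per class by
   default: associations are estimated within class, so a class-mean shift
   must not masquerade as outliers; a pooled mode exists. Groups with fewer
   than 3 (SD) or 4 (IQR) observed values are never flagged.
3. **Association.** Pearson, Spearman (Pearson on midranks; ties get average
   ranks), Kendall tau-b (tie-corrected, suited to quantized expression
   values), or plug-in mutual information in nats on equal-frequency bins
   with B = max(2, floor(log₂ n)) bins per axis. Quantile binning makes the
   MI estimate invariant under strictly monotone marginal transforms; the
   estimator is a documented choice, not a canonical one. Missing-data policy
   is pairwise-complete per pair per class (maximizes the effective n; the
   effective sample size actually used is carried through to every test).
4. **Tests.** One-sample Fisher Z per class (Pearson only):
   z√(n−3), two-sided normal. Two-sample Fisher Z:
   (atanh r₁ − atanh r₂)/SE with variance c/(n−d) per class, where
   (c, d) = (1, 3) Pearson, (1.06, 3) Spearman, (0.437, 4) Kendall — the
   classical Fieller–Hartley–Pearson large-sample constants. |r| within 1e−7
   of 1 is clamped before atanh (warning emitted). Mutual information has no
   analytic difference test; requesting MI without the permutation test is an
   error.
5. **Permutation test.** The null "no class difference in association" is
   generated by reassigning samples to classes with class sizes preserved;
   each sample's two gene values travel together, so within-sample gene–gene
   dependence is retained. p = (1 + #{|d*| ≥ |d_obs|})/(1 + B) (add-one, never
   zero). When the number of distinct label assignments C(n, n₁) ≤ B the
   distribution is enumerated exhaustively instead and the p-value is exact
   (the identity assignment guarantees p ≥ 1/C(n, n₁)). The adaptive mode is
   a sequential Besag–Clifford-style rule: stop at the h-th exceedance
   (default h = 10) with p = h/(draws used), else fall back to the add-one
   estimator at B_max (default 10,000). A permuted class with zero variance is
   redrawn up to 10 times, then counted as an exceedance (conservative).
   Exceedance comparisons use a 1e−12 slack so exact ties at |d_obs| (e.g. the
   complement assignment) are not lost to floating-point noise.
6. **Pair-subset selection for permutation.** Four modes: all pairs; pairs
   one-sample-significant in at least one class; pairs passing a two-sample
   Z prescreen; a user-supplied pair list. These are a reconstruction of the
   original tool's selection procedures, which are not fully specified in the
   available material; they must not be read as the original's exact rules.
7. **Multiple testing.** BH, Storey q-values, Bonferroni, Holm, Hochberg
   (step-up), applied separately per test family. Only the two difference
   families (two-sample Z and permutation) carry adjusted values into the
   output record, matching the output schema; the adjustment functions
   themselves accept any p-value family. Note the Hochberg identity on
   all-equal p-values: the step-up minimum sits at rank m, so Hochberg returns
   p itself while Holm/Bonferroni return m·p.

## Storey q-values

pi0 is estimated from the tail proportions #{p > λ}/((1−λ)m) over
λ ∈ {0.05, …, 0.95}, smoothed with a cubic least-squares polynomial and
evaluated at λ = 0.95; estimates above 1 are clamped to 1 (warning), and a
misbehaving fit falls back to pi0 = 1. The cubic LS fit is a deterministic
stand-in for a smoothing spline with similar effective degrees of freedom.
q = clip(pi0 · BH, 0, 1), so q ≤ BH whenever pi0 < 1. At m = 1000 a single
pi0 estimate has Monte-Carlo sd ≈ 0.1 under a uniform null; calibration
claims should therefore be made on averages over replicates, and the clamped
estimator's mean sits slightly below 1 by construction.

## Simulation framework

The generator emulates a two-class microarray experiment as G/2 disjoint,
mutually independent gene pairs, each drawn from a bivariate normal with
common marginal mean 8 and SD 1 (log₂-scale-like units) and a known
correlation per class. A fraction (default 0.5) of pairs are true DAPs with
correlations (r_i, r_j) in classes 1 and 2; the rest share r_null (default 0)
in both classes. Run k of a scenario uses the seed stream (seed, k), so every
scenario is exactly reproducible. The block-of-pairs structure is a
deliberate simplification: it does not model probe effects, heavier-tailed
noise, mean–variance coupling, or correlation *between* pairs, so passing
results demonstrate the statistical machinery's calibration and power under
the stated bivariate-normal conditions, not performance on any particular
platform's data.

Detection is scored with a pooled ROC: the two-sample p-values of all pairs in
all runs are swept jointly over thresholds (predict DAP when p ≤ t; tied
p-values enter together), AUC by the trapezoid rule, computed on *unadjusted*
p-values. Pooling across runs stabilizes the curve when each run contributes
only ~20 pairs; a per-run AUC can be had by scoring runs individually with
`compute_roc_auc`. Evaluation problem sizes used by the test suite and
`scripts/acceptance.py` — 40 genes per chip, 250 runs for power grids, 500
runs for null calibration, B = 1000 with 5 runs for p-value concordance — are
the package's standard evaluation conditions; the chip-size invariance result
is itself one of the checks (AUC moves < 0.05 between 20 and 80 genes).

Expected qualitative behavior, all verified by the acceptance tests: power
rises with n and with Δr = r_i − r_j; for fixed Δr = 1, asymmetric
coefficients (0.95, −0.05) beat symmetric ones (0.5, −0.5) because atanh
inflates z-scores for strong correlations and deflates them for moderate
ones; AUC is invariant to chip size and to scaling every gene's SD (Pearson
correlation is scale-free); Fisher Z p-values track permutation p-values
increasingly well as n grows.

## Numerical and design choices

- Canonical pair identity: lexicographically smaller gene ID first;
  duplicated and reversed pairs collapse, self-pairs are rejected. Output
  rows sort by ascending two-sample p (missing last), then pair IDs, making
  repeated runs byte-identical and diffable.
- File dialect: tab-delimited UTF-8 with header; "NA" is the sole missing
  token on output; "", "NA", "NaN", "null" (case-insensitive) are missing on
  input. Numerics are written with 6 significant digits (round-trip tested at
  that precision). Tab-delimited text is the canonical output; no spreadsheet
  writer is provided.
- Undefined estimates (zero variance, too few observations) are NaN/None and
  reported as "NA", never silently dropped mid-record; pairs failing the
  minimum-n rule are excluded and counted in the run report.
- Per-pair permutation streams derive from (seed, crc32(pair)), so p-values
  are independent of pair iteration order and stable across platforms.
- The scatter viewer separates a pure plot specification (point roles:
  normal / outlier-highlight / omitted; class palette blue circles vs black
  triangles, outliers red) from the matplotlib PDF backend, so display policy
  is testable without rendering. No per-class trend lines are drawn.
- The estimator follows scikit-learn conventions (`get_params`/`set_params`,
  clonable, fitted attributes with trailing underscores) and accepts either a
  samples × genes array/DataFrame with labels or an `ExpressionDataset`.

## Limitations

- Exactly two phenotypes; no multi-class extension.
- Analytic tests are large-sample approximations; at very small n, use the
  (exhaustive) permutation test.
- The Spearman/Kendall SE constants are asymptotic and can be mildly
  miscalibrated at n below ~10.
- MI differences are assessed only by permutation, and the MI estimator's
  plug-in bias makes small positive values at independence expected.
- No modeling of array-specific noise (background, probe effects) in the
  simulator; no partial correlations or network-pruning algorithms.
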