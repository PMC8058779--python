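# Methods

This document describes the statistical methodology implemented in
`modp`: the model pair, the modular optimal discovery procedure (mODP)
statistic, module clustering, the bootstrap empirical null, significance
measures, RNA-seq precision weights, default settings, and known
limitations.

## 1. Model pair

For each gene `i` with expression vector `y_i` over `n` measurements,
two nested Gaussian regression models are fitted by (weighted) least
squares:

- **null model** `mu0`: the mean structure common to all genes under no
  differential expression;
- **alternative model** `mu1`: the null structure plus the tested effect.

Three design kinds are supported (`design.build_study`):

- **static**: groups only. Null = intercept, alternative = group means.
- **independent**: a continuous covariate `x` (e.g. age, dose), modeled
  with a natural cubic spline basis of dimension `d`; with groups, the
  test is either a group difference in curves (`test="group-difference"`)
  or the curve effect itself (`test="covariate-effect"`).
- **longitudinal**: per-individual intercepts plus group-specific time
  curves.

Spline bases (`splines.spline_basis`) are natural cubic bases on `d+1`
knots at evenly spaced quantiles of `x`, yielding `d` basis columns with
the intercept kept separate; `d = 1` degenerates to a linear term. When
`d="auto"`, `fitting.select_dimension` extracts the top `E` eigen-genes
of the centered expression matrix and, for each, picks the dimension
minimizing exact leave-one-out cross-validated error (computed with the
hat-matrix shortcut); the final `d` is the modal choice. Cross-validated
arg-min selection occasionally over-selects by one; over-selection is
the safe direction for the bootstrap null (see §7).

Per-gene fits (`fitting.fit_all`) produce fitted means `mu0_hat`,
`mu1_hat` and maximum-likelihood scales `sigma0_hat`, `sigma1_hat`
(divisor `n`). Weighted fits use the `sqrt(w)` transform reducing WLS to
OLS; all downstream machinery operates on the transformed scale.

## 2. Null transform

The mODP operates on **null-transformed** data: each gene's null-model
fit is subtracted (`fitting.null_transform`), so that under the null
hypothesis the transformed data have mean zero. The alternative model is
refitted on the transformed data; the null model on transformed data is
the zero function. This puts all genes' null distributions on a common
footing so they can share an empirical null pool.

## 3. The mODP statistic

The optimal discovery procedure ranks genes by a ratio of summed
alternative likelihoods to summed null likelihoods, evaluated across the
*estimated models of all genes*. The full estimated-ODP statistic for
gene `i` costs `O(m)` likelihood evaluations; across genes, `O(m^2)`.

The modular approximation clusters the `m` fitted gene models into `K`
modules (§4), each with center `c_k` (average fitted alternative mean),
scales `upsilon1_k`, `upsilon0_k` (average fitted scales), and size
`|R_k|`. The statistic (`core.modp_statistics`) is

```
S(y) = logsumexp_k [ log|R_k| + logN(y; c_k, upsilon1_k^2) ]
     - logsumexp_k [ log|R_k| + logN(y; 0,   upsilon0_k^2) ]
```

costing `2Km` likelihood evaluations in total. With `K = m` and one gene
per module this is *exactly* the full estimated ODP (unit-tested to
1e-10), and the ranking is empirically stable in `K` (Spearman > 0.95
between `K=50` and `K=200` on a 4000-gene study).

## 4. Module clustering

`core.cluster_modules` is a k-means-style alternating algorithm under
the **symmetric Kullback–Leibler** distance between the per-gene fitted
Normal models `(mu1_i, sigma1_i)` and module models `(c_k, upsilon1_k)`.
Initialization draws `K` distinct seed genes; updates average member
parameters; empty modules are re-seeded from the worst-fit genes.
Degenerate genes (zero residual variance) are excluded from clustering
and reported with `p = 1`.

## 5. Bootstrap empirical null

P-values come from a pooled bootstrap null (`significance.bootstrap_null`):

1. Compute leverage-studentized alternative-fit residuals
   `r_ij = e_ij / sqrt(1 - h_jj)`, restoring the per-observation error
   scale.
2. For each of `B` iterations, draw one shared measurement-index sample
   (with replacement) applied to every gene, preserving cross-gene
   dependence; re-apply the null projection.
3. **Scale pinning**: rescale each resampled gene vector so its realized
   null-residual variance equals the gene's signal-free error-scale
   estimate `sigma1_hat^2 * n/(n-p1) * (n-p0)/n`. Resampling `n`
   residuals from an `n`-residual set adds a second layer of scale noise
   that over-disperses the pool (severely so for kurtotic count-scale
   residuals); pinning removes it while keeping the estimate signal-free
   for alternative genes.
4. Score the resampled data with a statistic that **mirrors the
   adaptivity** of the observed statistic
   (`core.modp_statistics_bootstrap`). The observed statistic of a gene
   is optimistically biased: the clustering assigned it the module whose
   parameters best match its own fitted model, and those parameters are
   member averages that include the gene itself. A frozen-dictionary
   bootstrap replicate carries none of that, making the pool
   stochastically too small and the p-values anti-conservative. So, with
   the module dictionary and the size weights frozen, each bootstrap
   gene is (i) re-assigned to the module nearest its own bootstrap
   refit, and (ii) scored against that one module with parameters
   re-formed as averages of the bootstrap refits assigned to it. When a
   module attracts more refits than its frozen size (null replicates
   cannot reach the dictionary's signal modules and crowd into the
   rest), the averaging is done within sub-groups of the frozen size,
   split in plain index order so no extra similarity selection is
   injected — only the observed averaging granularity is mirrored.
   Applied to the observed data this construction is the exact identity
   (unit-tested to 1e-12).
5. Pool all `m * B` replicate statistics; the p-value of each gene is the
   add-one empirical tail probability of its observed statistic in the
   pool.

Calibration (simulated independent-design studies): on a 2000-gene
global null, tail rejection rates are nominal at 0.05/0.01/0.005/0.001;
on the 20%-signal benchmark configuration the mean realized FDP of
q ≤ 0.1 calls is ≈ 0.08–0.09 over 100 studies.

## 6. Significance measures

- `estimate_pi0`: the smoother method — `pi0(lambda)` over a lambda grid
  with a df-3 natural cubic spline evaluated at the largest lambda;
  below 100 p-values, the fixed `lambda = 0.5` estimate.
- `qvalues`: step-up FDR with the `pi0` multiplier, enforced monotone.
- `local_fdr`: `pi0 / f_hat(p)` with the density `f_hat` from a
  Grenander (decreasing-density) estimator via isotonic regression.

## 7. Known limitations

- **Small, signal-dense studies.** When alternative genes occupy a large
  fraction of the module dictionary (observed at `m = 300`, 30% signal),
  null replicates crowd into the remaining modules at well above their
  frozen sizes. The granularity-matching in §5(4) removes most of the
  resulting deflation, but a residual downward bias in `pi0` remains and
  q-values can be anti-conservative. The procedure is designed for
  studies with thousands of genes; interpret results on a few hundred
  genes cautiously.
- **Mean-model underfit.** If the fitted spline dimension is below the
  true profile dimension, leaked signal inflates alternative genes'
  residual-scale estimates and corrupts the bootstrap scale pinning,
  deflating `pi0`. `d="auto"` avoids this (over-selection is harmless for
  calibration); fixing `d` manually below the truth is the one known way
  to break FDR control.
- **Power at high profile diversity.** The mODP's advantage over the
  F-test comes from shared profile shapes; as the number of distinct
  profiles approaches the number of genes, the advantage shrinks and can
  reverse at tight q cutoffs.

## 8. RNA-seq weights

`weights.estimate_weights` computes log-CPM (library size = column sum),
fits a lowess mean–variance trend to per-gene square-root residual
standard deviations against average log-CPM, and converts fitted
per-observation standard deviations to inverse-variance weights
(the standard precision-weighting approach for count data).
`filter_low_counts` removes genes below a minimum count. The weighted
pipeline applies the `sqrt(w)` transform before the mODP machinery; the
bootstrap mirrors the transform.

## 9. Comparators

`comparators` provides the partial F-test (exact p-values), the
moderated F-test (inverse-chi-square variance prior with
hyperparameters `(d0, s0^2)` estimated by moment matching on
log-variances; infinite-`d0` degenerate branch pools variances), and
bootstrap versions of both sharing the residual-resampling engine.

## 10. Simulation

`simulate.simulate_study` generates Gaussian studies: `U` distinct
dimension-3 spline profiles, per-gene scaled inverse-chi-square
variances (`d0=4`, `s0^2=1`), signal norm `snr * sigma * sqrt(N)`.
`simulate_counts` generates negative-binomial counts with a
depth-balancing constant added to alternative log-fold-changes so that
column-sum CPM normalization does not inject spurious group effects into
null genes. `evaluate` reports discoveries, realized FDP and power at
q-value cutoffs against the ground truth.
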