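# Methods

This document describes the statistical model, the estimators, every
user-facing parameter with its default and rationale, the synthetic-data
generator, the numerical choices, and the known limitations of `ruvmeth`.

## 1. Data model and assumptions

Samples are rows, features (CpG probes) are columns; all modelling happens
on the M-value scale, `M = log2((meth + offset) / (unmeth + offset))`,
which is unbounded and closer to homoscedastic than the beta scale. For
feature `g`:

```
y_g = Z a_g + x b_g + W alpha_g + eps_g
```

- `x` — the column of interest (group indicator or contrast), one column.
- `Z` — known covariates including the intercept.
- `W` — unobserved unwanted factors (batch, cell composition, …) shared
  across features; `alpha_g` are feature-specific loadings.
- `eps_g` — independent noise with feature-specific variance.

Rather than estimating `W` explicitly, the unwanted structure is absorbed
into a sample-by-sample covariance learned from negative controls:
features for which `b_g = 0` is credible a priori, so their
`Z`-residualized variation is (unwanted + noise) only.

Assumptions: controls share the unwanted structure of the other features;
the factor of interest enters through a single column; enough controls
exist for the empirical covariance to be informative (hundreds for
`n <= 100` samples).

## 2. Estimators

### 2.1 Control covariance

Let `R_c` be the control matrix residualized against `Z` only (not `x`:
removing `x` would also remove unwanted variation correlated with `x`,
precisely the part that must be corrected). Then

```
Sigma_c = (1/n_c) R_c R_c',    weight = (Sigma_c + lambda I)^-1.
```

`lambda = 0` when `Sigma_c` is well-conditioned. When `n_c < n` or the
condition number exceeds 1e12, the automatic ridge
`lambda = 0.1 * trace(Sigma_c) / n` is applied — large enough to make the
solve stable, small relative to the average per-sample variance. A user
override `ridge_lambda` is accepted everywhere the covariance is built.

### 2.2 GLS fit

With `M = [Z x]`, `theta_g = (M' S^-1 M)^-1 M' S^-1 y_g` where
`S = Sigma_c + lambda I`; the reported coefficient is the `x` component.
The solve uses one Cholesky factorization of `S` shared across all
features.

### 2.3 Inverse-method standard errors

Per-feature GLS variance formulas are unreliable here because `S` is
estimated and the noise is heteroscedastic across features. Instead, for
`b = 1..B` replicates:

1. draw `z_b ~ N(0, I_n)`, residualize against `[Z x]`, normalize to unit
   length (redraw if degenerate, up to `max_redraws` times);
2. fit `y_g` on `[Z z_b]` by the same GLS, keeping `gamma_hat(g, b)`.

Because `z_b` is orthogonal to the design, `gamma_hat` carries no signal —
only noise propagated through the same estimator. The standard error is

```
se_g^2 = kappa * mean_b gamma_hat(g, b)^2,
kappa  = a_X / mean_b v_b,
```

where `a_X` and `v_b` are the `x`-column (resp. `z_b`-column) diagonal
entries of the unit-noise sandwich `(M'S⁻¹M)⁻¹ M'S⁻¹S⁻¹M (M'S⁻¹M)⁻¹`. The
calibration constant `kappa` makes `E[se_g^2]` equal the true sampling
variance of `b_g` exactly under homoscedastic noise (verified to within
10% at `n = 50`, `m = 2000`, `B = 200` in the test suite), and it adapts
per replicate to how favourably each random column sits in the design.

`B` defaults to 50: the relative Monte-Carlo error of `se^2` scales as
`sqrt(2/B)` (~20% at B = 50), which perturbs ranks little since the same
replicates are shared by all features; raise `B` for reporting-quality
standard errors.

### 2.4 Inference

`t_g = b_g / se_g` with `df = n - rank(Z) - rank(X)` against a Student-t
reference. Edge cases: `se = 0` with `b = 0` gives `t = 0, p = 1`;
`se = 0` with `b != 0` gives `p = 0` plus a warning. FDR is
Benjamini–Hochberg (via statsmodels). Ranks order by ascending p, ties
broken by descending |t|, then lexicographic feature id — fully
deterministic.

### 2.5 Two-stage pipeline

- **Stage 1**: covariance from the platform negative-control block
  (`Y_inc`), fit all CpGs. The INC block and the CpG universe must be
  disjoint and share the sample order.
- **ECP selection**: `bottom_fraction` keeps the `floor(f * m)` features
  with the largest p-values; `fdr_cutoff` keeps features with
  `fdr > threshold`. Default: `bottom_fraction 0.5`. Studies with
  pervasive signal (cancer-like, ~40% of CpGs associated) should use the
  FDR rule or a smaller fraction; an empty selection raises an error
  suggesting a lower cut-off.
- **Stage 2**: covariance re-estimated from the ECP columns of `Y_cpg`
  itself; every CpG (including ECPs) is refit and reported.
- `iterations > 1` repeats selection + Stage 2 on the previous round's
  fit. Default 1; iteration rarely changes the ranking.
- If no platform controls exist, the pipeline can start at Stage 2 from a
  user-supplied control set (`initial_controls` / `--controls`).

Seeds: one master seed; Stage 1 uses `seed + 1`, Stage-2 round `k` uses
`seed + 1 + k`. Identical inputs and seed give byte-identical outputs.

### 2.6 Baseline comparator

`baseline_fit`: per-feature OLS on `[Z x]` followed by empirical-Bayes
variance moderation (moment matching on log residual variances, with a
Newton solve of the trigamma equation). Degenerate case: when all residual
variances are identical the moderated variances equal the observed common
value. This is the standard unadjusted analysis the pipeline is compared
against.

## 3. Preprocessing

- `m_from_intensities(pair, offset)` — M-values from raw channels;
  `offset` (default 100 intensity units) guards against zeros and must be
  positive when zeros are present.
- `filter_samples` — drop samples whose mean detection p-value exceeds
  `threshold` (default 0.01); refuses to drop everything.
- `filter_probes` — four rules: detection p above threshold in any
  retained sample; sex-chromosome location (X/Y, any common chromosome
  spelling); SNP at the CpG or single-base-extension site;
  cross-reactivity. Platform negative controls bypass the annotation
  rules (they have no meaningful genomic annotation). Reports per-rule
  counts; a probe failing several rules counts once in the total.

## 4. Synthetic-data generator

`simulate(SimulationParams)` draws, on the M-value scale:

```
Y = gamma + x beta + W alpha + eps
```

| parameter | default | meaning |
|---|---|---|
| n_samples | 60 | balanced two-group design |
| n_cpg_features | 2000 | tested universe |
| n_inc_features | 613 | platform negative-control block |
| p_true_positive | 0.05 | fraction of CpGs with nonzero beta |
| effect_size_beta | 1.0 | effect, M-units (±, random sign) |
| k_unwanted | 1 | number of unwanted factors |
| alpha_scale_cpg / _inc | 1.0 | loading scale on each block |
| confounding_rho | 0.0 | corr(W1, standardized x) |
| mislabel_fraction | 0.0 | fraction of observed labels flipped |
| noise_sd_median | 0.25 | per-feature noise sd, lognormal median |
| noise_sd_log_sigma | 0.3 | lognormal spread of the noise sd |

Baselines `gamma` are bimodal at ±3 M-units (mostly-methylated /
mostly-unmethylated probes); the INC block sits at −4 with no `beta`.
Confounding constructs `W1 = rho * x_std + sqrt(1 - rho^2) * noise`;
mislabelling flips only the *observed* labels handed to the analyst, the
truth set keeps the real ones. Presets: `clean` (no unwanted variation),
`batch_dominated` (strong orthogonal batch), `confounded_mislabel`
(rho = 0.6, 5% flips, effect 0.6 — the hard scenario), `high_dm` (40%
true positives). Problem sizes (m = 2000, n = 60) are chosen so the full
pipeline runs in well under a second while keeping `m >> n`.

Scope: the generator produces Gaussian M-values with linear factor
structure. It does not model probe-type chemistry differences,
beta-scale heteroscedasticity, spatial/chromosomal correlation, or
detection failures — it exists to validate the estimator, not to imitate
a scanner.

## 5. Evaluation and diagnostics

- RLE: per-sample five-number summary of deviations from per-feature
  medians; location-shift invariant.
- MDS: classical (Torgerson) scaling on Euclidean distances over the
  `top_n` most variable features (default 1000); eigenvalue shares
  reported; degenerate inputs return zeros with a warning.
- ROC/AUC via scikit-learn with score = −p (ties get half credit,
  matching the Mann–Whitney statistic); cumulative-true-positive curves
  over the deterministic ranking.

## 6. Numerical choices

- Cholesky (`cho_factor`/`cho_solve`) for all covariance solves; condition
  limit 1e12 triggers the automatic ridge.
- Established libraries are used for standard components — statsmodels
  for BH, scikit-learn for ROC, scipy for t/trigamma — while the
  RUV-inverse estimator itself is implemented here; brute-force oracles
  for GLS, BH and AUC live in the test suite.
- All randomness flows through `numpy.random.default_rng(seed)`; no global
  RNG state is touched.
- Output floats are written with `%.10g`, enough to round-trip ranks and
  make reruns byte-identical.

## 7. Limitations

- Single column of interest (`p = 1`); multi-coefficient contrasts are not
  supported by the inverse-method SEs as implemented.
- The SE calibration constant is exact under homoscedastic noise; under
  strong heteroscedasticity the SEs remain rank-preserving but
  individually approximate.
- With very few controls the empirical covariance is noisy; the GLS fit
  then deviates from OLS even when controls are pure noise. The relative
  deviation scales as ~`2 sigma_noise / sqrt(n_c)` divided by the RMS
  effect size, i.e. roughly 2% at `n_c = 10000` under default generator
  settings — increase the control count, not the ridge, when this
  matters.
- ECP selection inherits Stage-1 errors: if unwanted variation is so
  confounded that Stage 1 ranks true positives last, they can enter the
  control set. The fit is robust to a few percent contamination (the AUC
  typically moves by well under 0.02), but not to wholesale
  misspecification.
- No probe-type normalization, no cell-type deconvolution, no region-level
  (DMR) aggregation — per-CpG analysis only.
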