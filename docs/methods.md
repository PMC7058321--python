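# Methods

## Outcome model and priors

The outcome model is Bernoulli-logistic in the randomized allocation and
five baseline covariates, with categorical covariates (sex, nicotine
dependence, snuff use) dummy-encoded against their lowest level. Under the
default schema (5 dependence levels, 4 snuff levels) this gives K = 11
predictor columns: group, sex, years smoked, weekly cigarettes, four
dependence dummies and three snuff dummies.

Coefficients carry the plain horseshoe prior: β_k | τ, λ_k ~ N(0, (τλ_k)²)
with λ_k ~ C⁺(0, 1) and τ ~ C⁺(0, τ0). τλ_k is a **standard deviation**,
following the prior-recommendation literature this construction comes from.
Every encoded column gets its own local scale, including the allocation
column — the treatment coefficient is deliberately not exempted from
shrinkage. The intercept has a weakly informative Student-t(7, 0, 2.5)
prior. The global prior scale is

    τ0 = p0/(K − p0) · 2/√N,

with p0 the a-priori count of effectively nonzero coefficients (default
⌈K/2⌉: an agnostic midpoint between "nothing matters" and "everything
matters"), and 2 ≈ 1/√(p(1−p)) the pseudo-standard-deviation of a
Bernoulli observation at moderate p; the constant is fixed, not
configurable. Two notational ambiguities in the source formula are resolved
explicitly and kept switchable in `HorseshoeConfig`: `tau0_rule` selects
2/√N (default) versus 2/N, and `half_cauchy_scale_squared` selects whether
"C⁺(0, τ0²)" means scale τ0 (default; the squared symbol read as a
variance-style annotation) or literally scale τ0².

Continuous predictors are standardized to mean 0, sd 1 before fitting
(switchable). The horseshoe's single global scale is only meaningful when
columns share a common scale; binary/dummy columns are left as 0/1. The
standardization parameters are frozen in a `Standardizer` and re-applied
verbatim to held-out rows — they are never re-estimated on testing data.

## Posterior computation

`sample_posterior` is an exact Gibbs sampler assembled from three classical
augmentations, so every update is a closed-form draw and there are no
step-size or mass-matrix tuning choices:

* **Pólya-Gamma augmentation** (Polson–Scott–Windle) of the logistic
  likelihood: given ω_i ~ PG(1, η_i), the block (β0, β) is jointly Gaussian
  with precision Z'ΩZ + prior precision and is drawn by Cholesky solve.
  PG(1, z) variates come from Devroye's alternating-series rejection
  sampler, compiled with numba (~1 M exact draws/s); its first two moments
  are verified against the closed forms E = tanh(z/2)/(2z), Var(z=0) = 1/24.
* **Inverse-gamma scale-mixture expansion** (Makalic–Schmidt) of the
  half-Cauchy priors: λ_k² and τ² receive inverse-gamma conditionals via
  auxiliaries ν_k and ξ.
* **Student-t as a normal scale mixture** for the intercept, with an
  inverse-gamma mixing variance.

The chain targets exactly `exp(log_likelihood + log_prior)` as defined in
`horseshoe_model`; agreement of posterior means and interval endpoints with
deterministic 1-D and 2-D grid quadrature (within Monte Carlo error) is
asserted in the test suite. Defaults follow the analysis contract: 2000
retained draws, warmup equal to the number of retained draws, a single
chain. Diagnostics (bulk effective sample size and split R̂, the chain cut
in half; with `n_chains ≥ 2`, every chain split) are computed with arviz and
attached to the draws; any split-R̂ above 1.01 triggers a warning. All
randomness flows from one integer seed through `numpy.random.SeedSequence`
(the numba PG stream is seeded from the same sequence), so identical inputs
give identical draws. Degenerate designs (a constant predictor column) are
rejected before sampling, naming the column.

The known hard case for horseshoe posteriors — the funnel between τ and
near-zero coefficients — is handled here by the conjugate scale updates
rather than by reparameterized gradient steps; the scale conditionals are
exact inverse-gammas, so no positivity transform is needed.

## Synthetic trial generator

The generator emulates the published *shape* of the motivating trial: 1590
participants with exactly 827 allocated to intervention, ~70% female, a
binary prolonged-abstinence outcome with marginal prevalences 14.6%
(control) and 25.9% (intervention), and a covariate set that dummy-encodes
to K = 11. The covariate *marginals* were never published, so they are
invented but plausible and documented as such:

* years smoked ~ log-normal with mean 5 y, sd 3 y (students smoke few
  years); weekly cigarettes ~ log-normal with mean 50, sd 30;
* dependence (5 levels, probabilities .25/.25/.20/.20/.10) and snuff use
  (4 levels, .55/.20/.15/.10) cut from standard-normal latents correlated
  with log weekly cigarettes (ρ = 0.5 and 0.2) — heavier smokers trend
  toward higher dependence;
* log-odds coefficients: sex +0.15, years smoked −0.03/y, weekly cigarettes
  −0.008/cig, dependence dummies −0.15/−0.30/−0.45/−0.60, snuff dummies
  +0.10 — modest effects that create realistic baseline-risk spread without
  any covariate dominating.

The intercept and group coefficient are **not** hand-set: they are solved
by 1-D root finding (Brent, |prevalence error| < 1e-4) so that the inverse
logit averaged over a fixed 200 000-draw covariate sample hits the two
target prevalences. This makes the generator's true marginal risk
difference 11.3 percentage points by construction. With
`interaction_terms` empty the generating model is exactly the structural
form the analysis model assumes — a constant conditional odds ratio for
group — which is what makes the non-collapsibility checks sharp:
probability-scale effect gradients across strata then arise *only* from
baseline-risk variation. Optional `interaction_terms` add
group-by-predictor log-odds modifiers for explicit effect-modification
scenarios.

What the generator does **not** emulate: loss to follow-up (the analysis
table is complete by construction), measurement error in self-report,
within-participant correlation of any kind, or the real trial's unknown
covariate joint distribution. Passing calibration and recovery tests
therefore demonstrates the pipeline's internal correctness under a
well-specified data-generating process, not performance on the real trial
data (which are not available).

## Cross-validation and calibration

Ten folds are forced by the procedure's definition (90/10 splits with every
participant tested exactly once). Fold membership is a uniformly random
near-equal partition; per-fold sampler seeds derive deterministically from
(master seed, fold index). For each fold, dummy encoding and
standardization are fitted on the learning 90% only; the fold's posterior
(default 500 retained draws for the cross-validated studies — enough that
posterior-predictive means are stable to well under a percentage point)
feeds posterior-predictive probabilities for the held-out 10%. A test
asserts bit-identical fold draws when a held-out record is perturbed.

Calibration is assessed on the pooled held-out predictions (pooling before
smoothing). Bins are the ten equal-width probability intervals, half-open
with the last closed at 1.0; empty bins are reported with count 0, never
dropped. The lowess reliability curve uses smoothing fraction 2/3 and **no
robustness iterations**: with a binary outcome, the robustifying weights
treat every y = 1 residual as an outlier and drag the curve toward zero
(measured: max gap 0.38 with 3 iterations vs 0.03 without, on a pipeline
whose binned calibration was within 0.011 everywhere; 0.05 vs 0.016 on a
perfectly calibrated simulator at n = 10 000). Plain local linear smoothing
is the standard choice for binary calibration curves; both fraction and
iteration count remain arguments. Curves are clipped to [0, 1];
`max_calibration_gap` is the largest |smoothed − predicted| over the
observed prediction range.

The maximum-likelihood comparator refits the same model per fold with
unpenalized IRLS (statsmodels GLM). Folds showing (quasi-)separation —
non-convergence or any |coefficient| > 20 — are flagged with a warning and
their predictions clipped to [0.001, 0.999]. The comparator exists to
reproduce the qualitative contrast that plug-in MLE predictions are more
dispersed and less calibrated than posterior-predictive ones; this is
asserted as a variance inequality, not a curve match.

## Treatment effects

ITEs are computed from each participant's *held-out* fold model: the
participant's encoded row is pushed through `predictive_probability` twice
with the allocation column forced to 1 and to 0 (nothing else changes —
an intention-to-treat contrast, since randomization assigned the offer of
the intervention, not its use). The difference in percentage points is the
ITE; the mean ITE is the ATE, and it equals the size-weighted mean of
stratum CATEs as an exact identity. An all-data refit variant exists behind
`refit_all=True` for comparison only. Per-participant summaries default to
the point delta from averaged probabilities; central 90% intervals of the
per-draw deltas are available via `include_draw_intervals` (for the mean
the two averaging orders coincide; for ranges they do not, and the
per-draw-then-quantile order is used). CATE summaries stratify categorical
covariates by level and continuous ones by 10 quantile bins.

## Validation-study sizes and numerical choices

The packaged validation studies use sizes chosen to make their conclusions
statistically sharp while keeping the suite quick to run routinely:
quadrature comparisons at n = 100 and n = 50 with 3000–6000 draws and
3-MCSE margins; coverage of generating coefficients over 20 replicates at
N = 5000 with 400 retained draws; calibration and ATE recovery on the full
1590-participant trial with 500 draws and 10 folds; shrinkage separation
over 5 seeds at N = 2000. Root-finder tolerance for generator calibration
is 1e-10 on the prevalence scale; likelihood terms use `logaddexp` to avoid
overflow; `log_prior` returns −∞ (rather than raising) off the support so
samplers can reject.

The coverage study draws its generating truth sparse — group 0.715, sex
0.4, weekly cigarettes −0.012/cig, all other coefficients zero — i.e. a
truth consistent with the prior's sparsity assumption. This is deliberate:
the horseshoe is known to over-shrink coefficients of intermediate
magnitude (roughly one likelihood standard error from zero), and under the
default generator config, whose dependence dummies sit exactly in that
band, per-coefficient 95% coverage drops to ~70–80% even though the sampler
is exact — a property of the prior, not a computation error. The sparse
scenario isolates what the coverage test is meant to establish (correct
uncertainty propagation when the model is well specified); the
over-shrinkage behavior is recorded here as a known limitation.

## Known limitations

* Results on synthetic data bound what can be claimed: the real trial's
  covariate distributions, and hence its exact calibration curves and CATE
  point clouds, are not reproducible.
* Horseshoe intervals undercover for intermediate-magnitude coefficients
  (see above); effect summaries inherit mild shrinkage attenuation — the
  recovered ATE runs ~1–1.5 points below the generating 11.3 pp at the
  default sizes.
* The single-chain default matches the analysis contract; for publication
  use, `n_chains ≥ 2` gives more trustworthy R̂.
* Missing data are out of scope; the pipeline assumes a complete analysis
  table.
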