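# trialhte

Heterogeneous treatment effects in two-arm randomized trials with a binary
outcome, estimated with a Bayesian logistic regression under horseshoe
shrinkage priors.

## The problem

A randomized trial reports one average treatment effect, but individuals
differ: some benefit more from an intervention than others. Subgroup
analyses are fragile (arbitrary cuts, multiplicity, low power), so a more
principled route is to build a *prediction model* from the trial data,
verify that its predicted probabilities are **calibrated** on held-out
participants, and then read treatment-effect heterogeneity off
counterfactual predictions. `trialhte` implements that pipeline for a
two-arm smoking-cessation trial design: 1590 university students randomized
827:763 to a text-messaging intervention versus a waiting-list control,
with self-reported prolonged abstinence as the binary outcome (25.9%
prevalence under intervention, 14.6% under control; risk difference 11.3
percentage points, odds ratio 2.05). The original participant-level data
were never deposited, so the package ships a calibrated synthetic-trial
generator that reproduces the trial's structure and lets every stage run
and be tested end to end.

## The model

For participant *i* with allocation `G`, sex `S`, years smoked `Y`, weekly
cigarettes `W`, nicotine-dependence category `D` and snuff-use category `U`
(categoricals dummy-encoded to K = 11 predictor columns `x`):

```
y_i ~ Bernoulli(p_i),  logit(p_i) = β0 + x_i'β
β0        ~ Student-t(7, 0, 2.5)
β_k | τ, λ_k ~ Normal(0, (τ λ_k)²)      k = 1..K
λ_k       ~ Half-Cauchy(0, 1)
τ         ~ Half-Cauchy(0, τ0),   τ0 = p0/(K − p0) · 2/√N
```

the horseshoe prior: τ pulls all coefficients toward zero while the
heavy-tailed λ_k let genuinely informative ones escape. The prior guess of
the number of effectively nonzero coefficients is p0 = ⌈K/2⌉ = 6.
Posterior draws come from an exact Gibbs sampler (Pólya-Gamma augmentation
for the logistic likelihood, inverse-gamma scale mixtures for the
half-Cauchy and Student-t priors); see `docs/methods.md`.

The pipeline stages are:

1. **synthetic trial** — `default_trial_config` / `generate_trial`: exact
   arm sizes, ~70% female, and an intercept + group effect solved
   numerically so the marginal prevalences hit 14.6% / 25.9%;
2. **cross-validated calibration** — ten 90/10 learn/test splits so each
   participant is predicted exactly once out-of-fold; reliability assessed
   with ten probability bins and a lowess smooth, against a per-fold
   maximum-likelihood comparator;
3. **treatment effects** — each held-out participant is predicted twice,
   with the allocation column forced to 1 and to 0; the difference in
   percentage points is the individual treatment effect, summarized overall
   (ATE) and by covariate stratum (CATE).

## Worked example

```python
import trialhte as t

config = t.default_trial_config(seed=5)
records = t.generate_trial(config)
plan = t.make_fold_plan(len(records), 10, seed=5)

preds = t.crossval_predict(records, plan, n_draws=500, seed=5)
cal = t.assess_calibration(preds["p_hat"].to_numpy(), preds["outcome"].to_numpy())
print(f"held-out predictions: {len(preds)}")
print(f"max lowess calibration gap: {cal.max_calibration_gap:.3f}")

effects = t.individual_effects(records, plan, n_draws=500, seed=5)
print(f"ATE: {t.average_effect(effects):.1f} percentage points")
print(t.cate_by_covariate(effects, "dependence").strata.round(1).to_string(index=False))
```

prints

```
held-out predictions: 1590
max lowess calibration gap: 0.029
ATE: 9.9 percentage points
 stratum  mean_delta_pp  q05_delta_pp  q95_delta_pp  size
       1           11.5           8.8          13.6   418
       2           10.8           7.4          13.3   404
       3            9.5           5.8          12.2   275
       4            8.8           4.6          11.8   321
       5            6.9           2.2          10.5   172
```

Reading the output: every one of the 1590 participants received exactly one
held-out predicted abstinence probability, and the lowess reliability curve
never strays more than ~3 percentage points from the diagonal — the model's
probabilities can be taken at face value. The mean counterfactual contrast
(ATE) is ~10 percentage points, close to the generator's true marginal risk
difference of 11.3, with the usual mild attenuation from shrinkage. The
CATE table shows the predicted benefit falling from ~11.5 points at the
lowest dependence level to ~7 at the highest. Note the generating model
here has *no* group-by-dependence interaction: the gradient arises because
higher-dependence participants have lower baseline abstinence probability,
and a constant conditional odds ratio translates into smaller
probability-scale differences at lower baseline risk (non-collapsibility).

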