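# trialforest

Bayesian causal forests for randomized trials: heterogeneous, multi-arm and
time-varying treatment-effect estimation, with the surrounding toolkit a
trial analysis needs — estimand summaries, questionnaire scoring,
cardiovascular reactivity derivations, power calculations and synthetic-trial
generators for end-to-end testing.

## Who this is for

Researchers analysing randomized experiments — especially behavioural and
psychophysiological trials — who want treatment-effect estimates that (a)
adjust flexibly for covariates without hand-picking a functional form, (b)
shrink heterogeneous-effect claims toward homogeneity unless the data insist
otherwise, and (c) come as full posterior distributions rather than
point-plus-p-value.

## The model

For unit *i* observed at row *j*, the outcome is modelled as

```
y_ij = α_i + β(x_ij) + Σ_k τ_k(w_ij) · 1[z_i = k] + ε_ij,   ε_ij ~ N(0, σ²)
```

where

* `β(·)` is a **prognostic surface** over covariates *x*, a sum of 200
  regression trees with a BART regularization prior;
* `τ_k(·)` is a **treatment-moderation surface** over pre-randomization
  moderators *w* for treated arm *k* (two-arm trials have a single `τ`),
  a sum of 50 trees with a deliberately conservative prior — the prior
  s.d. of the effect at any moderator value is 0.3 outcome s.d. — so
  effects shrink toward homogeneity;
* `α_i ~ N(0, σ_α²)` is a per-person random intercept for
  repeated-measures designs (dropped automatically when every unit has one
  observation);
* `z_i ∈ {0..K}` is the randomized arm, 0 = control.

Fitting is by Gibbs sampling: Bayesian backfitting with
grow/prune/change Metropolis–Hastings moves for each forest (leaf
parameters integrated out of the acceptance ratio), conjugate normal draws
for leaves and intercepts, and conjugate inverse-gamma draws for σ² and
σ_α². Treatment coding is centred internally (z − 1/(K+1)) to decorrelate
`τ` from the intercept; reported `τ` draws are on the treated-minus-control
scale.

Two extensions:

* **Multi-arm trials** (`fit_multiarm_bcf`) — one moderator forest per
  treated arm, a shared prognostic forest, so the posterior supports per-arm
  effects and pairwise arm contrasts (`prob_difference`).
* **Targeted smoothing** (`fit_tsbcf`) — for repeated-measures series
  (e.g., minute-level cardiovascular recordings), every leaf of both forests
  holds a smooth function of time in a penalized cubic-spline basis, so the
  effect `τ(w, t)` is a continuous curve over the recording
  (`effect_curve`).

## Worked example

Simulate a two-arm trial of 1,000 students whose outcome is moderated by
baseline mindset indices, with a true effect of −0.39 s.d., then fit and
summarize:

```python
from trialforest import (BCFConfig, GeneratorTruth, fit_bcf, gen_cross_sectional,
                         average_effect, standardize, frequentist_crosscheck)

ds, truth = gen_cross_sectional(
    1000, truth=GeneratorTruth(true_ate_per_arm=(-0.39,)), seed=42)
cfg = BCFConfig(n_trees_prognostic=50, n_trees_moderator=20,
                draws=500, burnin=500, seed=0, keep_moderator_forests=False)
post = fit_bcf(ds, cfg)

ate = average_effect(post)
print(f"ATE = {ate.mean:.2f} [{ate.pct_10:.2f}, {ate.pct_90:.2f}] "
      f"(P(effect < 0) = {ate.prob_direction:.3f})")
std = standardize(ate, ds)
print(f"standardized: {std.mean:.2f} s.d. [{std.pct_10:.2f}, {std.pct_90:.2f}]")
ols = frequentist_crosscheck(ds)
print(f"OLS cross-check: {ols['coef']:.2f} "
      f"(95% CI {ols['conf_int'][0]:.2f} to {ols['conf_int'][1]:.2f})")
```

prints

```
ATE = -0.39 [-0.46, -0.32] (P(effect < 0) = 1.000)
standardized: -0.39 s.d. [-0.46, -0.32]
OLS cross-check: -0.46 (95% CI -0.58 to -0.33)
```

The first line is the posterior-mean average treatment effect with its
10th–90th percentile interval and the posterior probability the effect is
beneficial (negative here: the outcome is coded so lower is better); the
second expresses it in pooled-s.d. units; the third is the
heteroskedasticity-robust OLS difference for sanity (it does not adjust for
covariates the forest uses, so the two need not coincide exactly).

A command-line surface covers the same pipeline: `trialforest simulate`,
`trialforest fit`, `trialforest summarize`, `trialforest power`,
`trialforest score` (see `trialforest --help`).

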