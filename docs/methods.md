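# Methods

This note documents the statistical machinery in `trialforest`: the model,
its priors and defaults, the synthetic-data generators used for testing,
numerical choices, and known limitations.

## Outcome model

For unit *i* at observation row *j*:

```
y_ij = α_i + β(x_ij) + Σ_k τ_k(w_ij) · 1[z_i = k] + ε_ij,  ε_ij ~ N(0, σ²)
```

* `β(·)` and each `τ_k(·)` are sums of binary regression trees. Split rules
  are `value < threshold` for numeric variables (boundary values route
  right) and subset membership for categoricals. Numeric split candidates
  come from a 100-point quantile grid of the observed values, which makes
  the candidate set deterministic given the data.
* `α_i` is a normal random intercept; when every unit contributes exactly
  one row it is not identified separately from ε and is fixed at zero
  (σ_α = 0).
* Arms are coded 0..K with 0 = control. Internally each moderator forest's
  contribution is multiplied by `1[z = k] − 1/(K+1)` (centred coding), which
  decorrelates the effect surface from the intercept; the reported `τ_k`
  draws are the forest outputs themselves, i.e. arm-k-minus-control in
  outcome units. The reported prognostic draw `mu` is defined as the
  control-arm conditional mean (including the centring offset), so
  `alpha + mu + Σ_k tau_k·1[arm = k]` reconstructs each draw's fitted mean
  exactly — this identity is what `BCFPosterior.fitted_draws` returns and
  tests assert.

## Priors and defaults

All scales below are relative to the outcome, which is internally
standardized before fitting and rescaled afterward.

| parameter | default | meaning |
|---|---|---|
| prognostic trees | 200 | capacity of `β` |
| moderator trees | 50 | capacity of each `τ_k` |
| `leaf_scale_prognostic` | 1.0 | prior s.d. of `β` at a point (spread over trees as `1/√m` per leaf) |
| `leaf_scale_moderator` | 0.3 | prior s.d. of `τ` at a point — the conservative, homogeneity-shrinking choice |
| depth prior | a = 0.95, b = 2 | P(split at depth d) = a(1+d)^−b, both forests (separately configurable via `moderator_depth_prior`) |
| proposal probabilities | 0.28 / 0.28 / 0.44 | grow / prune / change |
| minimum leaf size | 5 rows | support constraint on proposals |
| σ² prior | IG(ν/2, νλ/2), ν = 3 | λ set so P(σ < sd(y)) = 0.9 a priori |
| σ_α² prior | IG(2, 0.05·var(y)) | weak; the data dominate with ≥ tens of units |
| draws / burn-in / thin | 2000 / 1000 / 1 | retained Gibbs sweeps |

The grow/prune acceptance ratio uses the marginal likelihood with leaf
parameters integrated out; the uniform rule-selection probability appears
in both the proposal and the structure prior and cancels, which is what the
brute-force enumeration test verifies on a four-row instance.

Conservatism intentionally biases heterogeneity toward zero in small
samples: with a 0.6 s.d. binary effect jump, the fitted subgroup gap is
roughly half its true size at n = 1,000 and approaches the truth by
n = 4,000. The acceptance suite therefore exercises moderation recovery at
n = 4,000; this is a statement about the prior's designed behaviour, not a
convergence failure.

## Imputation and intent-to-treat

Rows are analysed for all randomized units that provided outcomes. Missing
covariate or moderator cells are completed deterministically (numeric:
median; categorical: mode) and each imputed variable gains a
`<name>_missing` indicator covariate. Deterministic single imputation keeps
fits exactly reproducible; multiple imputation is out of scope. Because all
supported designs are randomized, no propensity score is estimated —
`include_propensity=True` merely appends the constant-by-design assignment
probability as a covariate.

## Multi-arm extension

Each treated arm gets an independent moderator forest with the identical
conservative prior; the prognostic forest and variance components are
shared. With K = 1 the sampler is literally the two-arm code path, so the
reduction consistency check is exact. Arm contrasts are summarized by
`prob_difference`, the fraction of draws in which ATE_a − ATE_b has the
stated sign, with exact ties contributing half.

## Targeted smoothing

For series data, leaf parameters of both forests become coefficient vectors
on a basis over standardized time `[0, 1]`: an intercept column plus a
cubic B-spline design (default 4 interior knots at time quantiles) with
training-mean-centred columns. Leaf priors are diagonal normal: the
intercept weight has s.d. `leaf_scale`, spline-deviation weights have s.d.
`leaf_scale / smoothness_scale`. `smoothness_scale` is therefore a
shrinkage strength — the default 2 makes within-leaf time variation half as
large as the level a priori, and `smoothness_scale → ∞` recovers the
time-constant model exactly. Leaf updates are conjugate multivariate
normal; the marginal-likelihood score generalizes the scalar formula with
the same cancellation structure.

Recording epochs are summarized by window-averaging the fitted curve;
baseline subtraction (reactivity) happens upstream in the physiology layer,
and model fits use post-randomization (active-epoch) rows, since the
baseline epoch precedes randomization and carries no effect by design.

## Estimands

* ATE/CATE: per draw, average the effect surface over the (subset of) rows;
  report mean, 2.5/10/90/97.5 percentiles and the directional posterior
  probability (ties at zero split evenly).
* Standardization divides by the pooled s.d., defined as the square root of
  the equally weighted average of arm-level observation variances.
* The manipulation check passes when the 10th–90th interval excludes zero
  in the beneficial direction or the standardized magnitude reaches
  0.25 s.d.
* The subgroup cut-point search scans a 50-point quantile grid of a
  continuous moderator and maximizes the difference in the posterior-mean
  *control-condition* outcome surface between the induced groups (≥ 10
  units per side). It never reads the effect draws — a blinding contract
  verified by permutation — and flags objectives below a quarter of the
  outcome s.d. as weak separation. The exact published variant of this
  algorithm is not fully specified; this objective is a documented
  reconstruction with the same blinding property.
* The frequentist cross-check is OLS with HC2 (or cluster-robust-by-unit)
  errors; perfectly collinear covariates are dropped with a warning.

## Power calculations

Two methods, because published design figures mix exact software output
with approximations: `noncentral_t` computes two-sample t-test power from
the noncentral t distribution (df = 2n − 2, noncentrality d√(n/2)) and
integer-searches the smallest n reaching the target; `normal_approx` uses
n = 2((z₁₋α + z₁₋β)/d)², rounded up. At extreme noncentrality where the
nct tail is numerically unstable the normal tail limit is substituted.

## Synthetic-data generators

The generators define the study conditions the engine is tested under, and
return their ground truth for self-contained recovery tests. Outcomes are
scaled so the marginal s.d. is ≈ 1 under a null truth; effects are on the
standardized scale.

* **Cross-sectional** — one row per unit; simple random assignment with
  equal cell probabilities; baseline fixed-mindset and stress-mindset
  indices on 1–6 scales (clipped normals around 3.5) plus their product as
  moderators; the prognostic surface loads 0.3 on each index; default ATE
  −0.39 s.d. An optional moderation function adds effect heterogeneity; the
  shipped default (`mindset_moderation`) strengthens the effect above the
  midpoint of the product term.
* **Daily diary** — 4–5 school days × two reports; person intercepts
  (s.d. 0.6); day-level stressor intensity on 1–5 with a 0.30 point mass at
  1 (no-stressor days); negative self-regard (1–7, higher = worse) responds
  to intensity with slopes calibrated analytically so pooled correlations
  hit 0.38 (control) and 0.19 (treated); cortisol is generated on a
  standardized log scale with within-day decline, a −0.23 s.d. treatment
  main effect, and no intensity correlation.
* **TSST series** — per-minute standardized outcome with a control epoch
  profile peaking at the speech epoch, unit intercepts, a smooth
  arm-specific effect curve (zero during the pre-randomization baseline; the
  default profile peaks at −0.44 s.d. in the speech epoch), and both raw and
  baseline-subtracted reactivity columns.

What they do not emulate: school/cluster sampling, item-level responses,
informative missingness, diurnal cortisol outside school hours, or serial
correlation in the minute-level noise beyond the unit intercept. Passing
recovery tests therefore demonstrates correctness of the estimator under
its own assumptions, not robustness to those real-data features.

## Numerical choices

* All randomness flows through one `numpy.random.Generator` per fit, seeded
  from the config; same data + config + seed is bitwise reproducible.
* Pruned tree nodes are tombstoned rather than re-indexed, keeping row→leaf
  membership ids stable; draws are stored as compacted alive-node arrays.
* Categorical split subsets are stored as int64 bitmasks (≤ 63 levels);
  unseen levels at prediction time route to the larger child with a
  warning.
* σ² is floored at 1e−8 at initialization so degenerate (constant) outcomes
  fall back to the prior rather than dividing by zero.
* Problem sizes in the test and acceptance suites (e.g., 50 calibration
  replicates at n = 300 with 30/12-tree forests; moderation recovery at
  n = 4,000) were chosen so each check's Monte-Carlo noise is well inside
  its tolerance while a full run stays in the minutes range on one CPU.

## Known limitations

* No autoregressive residual structure in the time-series extension.
* Deterministic single imputation understates imputation uncertainty.
* The conservative moderator prior under-reports heterogeneity magnitude in
  small samples by design (see above).
* Interval coverage for the null ATE at short chain lengths runs a few
  points under nominal (≈ 76–78% for the 80% interval in the calibration
  suite).
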