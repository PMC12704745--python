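# Methods

This note documents the models implemented in `bodymeta`, the assumptions
behind them, the numerical choices, and what the synthetic-data validation
does and does not establish.

## 1. Task structure and data model

One trial of the two-rubber-hand paradigm yields: the side whose fake hand
was tapped synchronously with the hidden real hand (`sync_side`), the 2AFC
ownership report (`response_side`), a 3-point PAS clarity rating, a decision
response time, a post-decision (PAS) response time, and a censoring flag for
speeded trials that hit the stimulation ceiling.  The canonical interchange
format is a comma-delimited table with the fixed header
`subject, experiment, asynchrony_ms, n_touches, sync_side, response_side,
pas, rt_decision_s, rt_postdecision_s, censored`.

"Hit" means choosing the right hand when the right hand was the synchronous
one; "false alarm" means choosing it when the left hand was synchronous.

## 2. Type-1 signal detection

Equal-variance Gaussian SDT with the 2AFC convention:

    d' = (1/sqrt(2)) [Z(P_hit) - Z(P_fa)],
    C  = -(1/2) [Z(P_hit) + Z(P_fa)].

With our hit definition, positive C is a conservative shift away from
"right" responses.  When any empirical rate is 0 or 1, the log-linear rule
(add 0.5 to each of the four type-1 cells) is applied before the quantile
transform and flagged in the result; the rule was chosen because it is the
most widely used correction and keeps estimates finite — which correction
(if any) the original analyses used is not stated, so this is a documented
package choice.  An unscaled (yes/no) variant is exposed via
`dprime_2afc(..., scaled=False)` but is never the default.

## 3. Meta-d' by maximum likelihood

The meta-d' model asks what type-1 sensitivity an SDT-ideal observer would
need to generate the observed response-conditional rating counts.  Internal
evidence is unit-variance Gaussian with separation `sqrt(2) * d'` (so that
the 2AFC-convention d' is recovered); the meta-level model keeps the type-1
criterion at its observed *relative* position c' = C / (sqrt(2) d') and
frees a single meta-d' shared across response sides plus
2 x (n_ratings - 1) ordered type-2 criterion offsets.  The fit maximises
the multinomial likelihood of ratings conditional on response, with
probabilities normalised within response under the meta-level model.

Numerics: type-2 cells are padded by 1/(2 x n_ratings) before the MLE
(standard practice; keeps the likelihood finite when cells are empty);
criteria offsets are optimised on a log scale by bounded L-BFGS-B from five
deterministic starts spread over plausible efficiency levels; ties are
broken by likelihood, then by smaller |meta-d'|.  M-ratio = meta-d'/d' is
scale-invariant, so the 2AFC convention does not affect it.  The test suite
checks the optimum against a brute-force two-stage grid scan over meta-d'
with criteria re-optimised at every node.

## 4. Hierarchical Bayesian group M-ratio

Joint model over all conditions:

    log M_sc ~ Normal(mu_c, sigma_c)      (subject s, condition c)
    mu_c     ~ Normal(0, 1)
    sigma_c  ~ half-Normal(1)

with the cell likelihood given by the meta-d' observation model at
meta-d' = exp(log M_sc) * d'_sc, type-1 parameters fixed at their point
estimates.  Two deliberate choices:

* **Profile likelihood for the type-2 criteria.**  Rather than sampling
  each subject's criteria, the per-cell profile log-likelihood of log M
  (criteria maximised at 19 grid nodes over log M in [-4, 1.6], warm-started
  with a cold-restart guard, densified by shape-preserving PCHIP
  interpolation) is precomputed, making each MCMC likelihood evaluation an
  interpolation look-up.  This empirical-Bayes-style profiling slightly
  understates criterion uncertainty but leaves the group-level posterior
  essentially unchanged at the cell sizes used here (recovery within 0.02
  of truth at 30 subjects x 200 trials); it is what makes the joint model
  cheap enough to calibrate by repeated simulation.  PCHIP (not a cubic
  spline) matters: splines overshoot where the profile falls steeply and
  can create spurious likelihood spikes that trap chains.
* **No zero-cell padding.**  The exact multinomial likelihood is finite
  without padding, and padding (needed only for the MLE) biases group
  M-ratio downward by about 0.08 at 200 trials/cell.

Sampling is Metropolis-within-Gibbs, vectorised across chains: elementwise
adaptive random walks on the conditionally independent subject effects, a
conjugate Gaussian draw for mu_c, stepping-out slice sampling for sigma_c,
plus two non-centred moves per iteration — a joint translation of
(mu_c, all its subject effects) and a joint scale move of
(sigma_c, the subject-effect deviations) — which defeat the hierarchical
funnel that otherwise freezes sigma when the true between-subject spread is
near zero.  Defaults mirror the study configuration (3 chains x 10,000 kept
iterations, 1,000 burn-in); `MCMCConfig.scaled_down()` (3 x 2,000, 500
burn-in) is used in tests.  Convergence is reported as rank-normalised
split R-hat and ESS (arviz); an R-hat above 1.05 on any group mean attaches
a warning and suppresses credibility calls.  Condition contrasts are
posterior differences of mu_c in log units with 95% HDIs; an interval
excluding zero is a credible difference.

## 5. Drift-diffusion model and v-ratio

Decision stage: Wiener process with diffusion scale fixed at s = 1 (one of
the two standard conventions; all drifts and boundaries are in that scale),
drift v per asynchrony condition signed by the stimulus, boundary
separation a, relative start w, nondecision time t0.  Inter-trial
variability parameters (sv, sz, st) are deliberately excluded — the model
space is z/w, t0, v, a.  First-passage densities use the small-time /
large-time series with per-element regime selection and term counts chosen
for truncation error below 1e-7; correctness is checked against the
closed-form absorption probability

    P(upper) = (1 - exp(-2 v w a)) / (1 - exp(-2 v a))

and against large Euler simulations.

Post-decisional stage: after the boundary is hit, accumulation continues
for the observed post-decision interval tau (capped at the 3-s PAS window)
with drift v_post keeping the stimulus-defined sign.  Measured toward the
chosen boundary, the increment is Normal(+v_post tau, tau) after correct
decisions and Normal(-v_post tau, tau) after errors; two fitted cut-points
turn it into PAS 1/2/3.  The efficiency index is

    v-ratio = v_post / v,

with drifts signed toward the correct boundary before the ratio, so
informative confidence gives a nonnegative ratio; v_post = 0 is a rating
that ignores the accumulated evidence.  `VRatioModel` fits decision and
confidence stages jointly by maximum likelihood (they factorise given
correctness and tau); pooled-drift and per-condition-drift modes are both
available because it is ambiguous which the original analysis used —
pooled is the default and the per-condition mode divides by the mean drift
magnitude.

Hierarchical DDM: subject-level (v per condition, log a, logit w, log t0)
from Gaussian group distributions; blocked adaptive Metropolis (elementwise
drift updates exploiting disjoint condition trial sets; one joint a/w/t0
block per subject), conjugate group means, slice-sampled group spreads, and
non-centred translation moves for the group means.  Chains start from
jittered per-subject maximum-likelihood fits; per-trial log-likelihoods are
cached so one iteration costs five density passes.  The convergence bar for
group drifts is R-hat < 1.02, matching the stricter hierarchical-DDM
convention.

## 6. Group statistics

* `rm_anova_gg`: one-way repeated-measures ANOVA by direct sums of squares;
  Greenhouse-Geisser epsilon from the double-centred condition covariance;
  dfs multiplied by epsilon whenever epsilon < 1 (k > 2); partial eta
  squared = SS_effect / (SS_effect + SS_error).  `mixed_anova_gg` extends
  this with one between-subject factor (pooled epsilon for within effects),
  used for cross-experiment comparisons.
* `bayes_t_one_sample`: JZS Bayes factor by quadrature of the noncentral-t
  likelihood over the Cauchy(0, r) effect prior, r = 0.707 by default; the
  directional BF+0 integrates the positive half-prior; a robustness sweep
  over a prior-width grid is available, and `sequential_bf` is a thin loop
  over accumulating subjects in ID order (presentation only).
* `bf_oneway_rm`: BF01 comparing the subject-effects-only null with the
  condition-effect model under g-priors (multivariate-Cauchy reading:
  g ~ InverseGamma(1/2, r^2/2), r = 0.5 for the orthonormalised fixed
  condition contrasts, r = 1 for random subject effects; the "uniform
  priors" wording in the source description is internally tense and this
  conventional reading is adopted).  In the balanced design the subject and
  condition contrast subspaces are mutually orthogonal projections, so the
  marginal likelihood is closed-form per g-draw; the integral over g uses
  20,000 seeded stratified (Latin-hypercube) draws, giving Monte-Carlo
  error below 0.02 in log BF.
* `nonparametric_tests`: Kolmogorov-Smirnov normality check on z-scored
  values per group plus Kruskal-Wallis across groups (scipy).

A note on decision rules: the pipeline summary counts a condition as
showing "credibly positive d'" only with strong Bayesian evidence
(BF+0 > 10) together with p < .05 one-sided.  With five conditions, the
weaker moderate-evidence rule (BF+0 > 3) would false-claim on 7-10% of
null datasets at any sample size, making null-template calibration
uninterpretable; strong evidence keeps the familywise false-claim rate
near 2% per run.

## 7. Synthetic observers (what they emulate, and what they do not)

**SDT observer.**  Decision evidence X ~ Normal(s * delta/2, 1) with
delta = sqrt(2) d' and s = +/-1 the synchronous side; response "right" iff
X > C.  The PAS comes from a second look at the stimulus on a meta evidence
axis with sensitivity m * delta (m = target M-ratio), sampled *conditioned
on agreeing with the committed response* relative to the equivalently
placed meta criterion, then cut at the type-2 criteria.  This
truncated-sample construction is the exact generative counterpart of the
meta-d' observation model, so refitting recovers meta-d' = m d' for any
m > 0 (including m > 1, the super-ideal regime).  A simpler additive-noise
construction ("confidence = decision evidence + independent noise, variance
inflated to hit the target") was tried first and rejected: because the
response is conditioned on a different sample, its effective type-2
sensitivity falls well below m d' (a generative M-ratio of 0.7 refits to
about 0.51), which would have broken every recovery-based check.  Lapses
replace both the response and the rating by uniform draws.  Defaults
emulate the study conditions: asynchrony set {18, 31, 52, 88, 150} ms with
d' = {0.1, 0.45, 0.8, 1.3, 1.7} (near chance at 18 ms, clearly above from
~30 ms), M-ratio 0.7 (the typical 0.6-0.8 range for this paradigm),
touch-count gains {3: 0.65, 6: 1.0, 9: 1.15}, 300 trials per session
(Exp 1/2 templates) and 480 for the speeded template; the rotated-hands
control preset sets d' = 0 everywhere and the simultaneity-judgement
control keeps graded d' with lower efficiency (0.45).

**Diffusion observer.**  Euler-Maruyama integration at 1 ms steps with the
Brownian-bridge within-step crossing correction (a step that stays inside
the boundaries still crosses with probability exp(-2 d d'/(s^2 dt))); the
correction removes the leading overshoot bias, which at 10^6 trials would
otherwise exceed Monte-Carlo error and visibly distort the RT histogram.
Trials with no passage inside the stimulation ceiling are emitted with
`censored = True` (response read from the current evidence sign) and
excluded by default downstream — how such trials were scored originally is
not stated, so exclusion is the documented default.  The post-decisional
stage uses the exact Gaussian increment (no boundary), matching the
v-ratio observation model.

**Limitations of the emulation.**  Homogeneous observers within a
simulated group (no between-subject parameter spread beyond sampling
noise); no lapses in the diffusion observer; no RT contaminants, no
collapsing bounds, no inter-trial parameter variability; unspeeded RTs are
schedule filler (lognormal draws), not modelled quantities.  Passing
recovery tests therefore shows the estimators are correct and calibrated
under their own assumptions — it does not certify robustness to the model
violations real data bring (criterion drift, attention lapses, RT
outliers).

## 8. Problem sizes used in validation

The validation suite runs at deliberately chosen sizes: chance-level and
ideal-observer checks at 20,000 trials; meta-d' grid-scan equivalence on 50
random 500-trial tables; M-ratio recovery at 10,000 trials (MLE) and 30
subjects x 200 trials (hierarchical, 3 x 2,000 MCMC); null calibration
over 20 datasets of 10 subjects x 5 conditions x 120 trials; density
validation against a 10^6-trial simulation; hierarchical DDM recovery at
20 subjects x 400 trials; v-ratio recovery at 2,000 trials per setting;
statistics calibration at 10,000 null replicates.  The hierarchical
defaults (3 x 10,000 iterations; 20,000 samples for the DDM analogue)
remain available for production runs via `MCMCConfig`.
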