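# Methods

## The model

`semicr` implements a fully parametric five-state model for cohorts in which
a non-terminal illness (here: cognitive impairment, CI) is observed only at
scheduled interviews, death times are exact (registry flagging), and
participants can stop attending interviews for reasons plausibly related to
the illness itself.  The states are

    H  (healthy)           CI     (cognitively impaired)
    LTF (lost to follow-up while healthy)
    CILTF (impaired and lost to follow-up)
    D  (dead, absorbing)

with eight transitions:

    1: H->D    2: H->CI     3: CI->D    4: H->LTF
    5: LTF->D  6: LTF->CILTF  7: CILTF->D  8: CI->CILTF

Drop-out is modelled *explicitly* as two latent-ish states rather than as
censoring, so informative loss to follow-up (LTF) becomes a testable model
feature instead of an untestable assumption.  The CI->CILTF transition is
needed because, with interval censoring, a participant may have become
impaired between their last healthy interview and the missed one.

All intensities run on the global clock t = years since study entry (a
Markov, clock-forward timescale) and are Weibull proportional hazards:

    lambda_m(t | x) = tau_m * alpha_m * t^(alpha_m - 1) * exp(x' beta_m)

with covariates x = (centred baseline age in years, female indicator).  A
form in which the rate-scale multiplies the shape (`tau * alpha * t^(alpha-1)`
rather than `tau * t^(alpha-1)`) is used; this is purely a reparameterisation
of the intercept and does not change fits, but it is the convention every
reported intercept in this package follows.  Baseline impairment at the
prevalence screen follows a logistic model in the same covariates.

### Identifiability constraints and the sensitivity constant k

Transitions 6 and 7 involve states that are never directly observed for
initially-healthy participants, so two constraints are imposed:

* `lambda7 = lambda3` — death of an impaired participant does not depend on
  whether they have dropped out;
* `lambda1 * lambda6 = k * lambda2 * lambda5` — the ratio of the death
  hazard to the impairment hazard before drop-out is `k` times the same
  ratio after drop-out.

The constant `k > 0` carries no information in the data and is **fixed**,
never estimated.  `k = 1` (the default) still allows informative LTF — both
hazards may change after drop-out, in proportion; `k > 1` means the
impairment rate rises more than the death rate after drop-out.  The derived
transition 6 is itself Weibull-type with effective shape
`alpha2 + alpha5 - alpha1` (which must be positive; parameter sets violating
this raise a `DegenerateConstraintError`), effective rate-scale
`k * tau2 alpha2 tau5 alpha5 / (tau1 alpha1 (alpha2+alpha5-alpha1))` and
coefficient vector `beta2 + beta5 - beta1`.

## The likelihood

Each subject's record collapses to one of 12 observable routes (see
`semicr.likelihood`).  A route probability sums over all latent trajectories
compatible with the observations; because any observation gap can hide at
most two latent transitions before reaching an absorbing or
terminally-latent state, every kernel is an at-most-doubly-nested time
integral of closed-form sojourn survivals and intensities.  Alive routes
contribute probabilities; routes ending in death contribute a density in the
exact death time.

Two recursions organise the kernels: `A(state, s, T)`, the probability of
being in *any* live state at the end of follow-up given occupancy of `state`
at `s` (everything after the last observation is unconstrained), and
`D(state, s, d)`, the sub-density of death at `d`.  Observable-LTF routes
additionally restrict the latent entry into {LTF, CILTF} to the interval
between the last attended and the first missed interview.

When impairment was confirmed at later interviews (last attended time
b' > first detection b) the continuation starts from b' with an occupancy
factor S_CI(b, b'): a latent CI->CILTF move before b' would have produced a
missed interview and hence a different route, so starting the continuation
at the earlier time would disagree with the observation scheme (the
simulator makes this check concrete).

### Numerical evaluation

Integrals use fixed-order Gauss–Legendre quadrature — deterministic and
smooth in the parameters, which quasi-Newton optimisation requires.  Shapes
below one make the intensity integrably singular at t = 0; every integral is
therefore evaluated after the power substitution `z = t^alpha_m` of the
intensity attached to the integration variable, which removes the
singularity exactly and reduces to the plain rule when `alpha_m = 1`.

Default orders: 16 nodes per dimension for stand-alone evaluation, 8 for
fitting (`FitOptions.quad_nodes`).  On a simulated cohort the total
log-likelihood changes by about 1e-3 (of several thousand) between 8 and 32
nodes, i.e. per-subject error around 1e-6; the test suite pins this
convergence.  The engine carries a parameter-set axis alongside the subject
axis, so finite-difference gradients (28 points) and Hessians (~1.5k points)
are evaluated as vectorised batches rather than one call per point.

### The two-year rule

Because a healthy-to-death observation must sum over latent CI/LTF detours,
a near-zero direct H->D rate can be compensated by inflated later death
rates, producing unfeasible high-likelihood parameter sets.  The engine
therefore supports the restriction that subjects who died within 2 years
(boundary included) of their last attended interview made no latent
transition in between: routes 3, 4 and 8 then use the direct death kernel,
and route 6 keeps only its observed H->LTF->D path (the observed LTF cannot
be annulled; routes 10 and 12 already have a single latent structure).  The
flag defaults on, matching the intended analysis protocol for real data.
Simulation studies in this package fit with the rule **off**: the simulator
has no such restriction, and the oracle checks validate the exact
likelihood; the rule is a robustness device, not part of the
data-generating process.

Records with exactly zero probability are floored at 1e-300 with a warning
listing the subject ids (or raised under `strict=True`); they indicate
data/model inconsistency rather than a fit failure.

## Inference

The free vector stacks, per free transition (1, 2, 3, 4, 5, 8):
`log tau, log alpha, beta_age, beta_sex`, then the three logistic screen
coefficients — 27 entries.  Optimisation is L-BFGS-B on the unconstrained
scale (positivity via logs), forward-difference gradients (step 1e-6),
gradient tolerance 1e-5, at most 500 iterations.  Default initial values are
crude: event-count/exposure rates per transition family, unit shapes, zero
coefficients, and a logistic regression (statsmodels GLM) for the screen
model; on simulated cohorts this start reaches the same optimum as starting
at the generating values.

Standard errors invert a central-difference Hessian of the negative
log-likelihood at the optimum (relative step 1e-5); a non-positive-definite
Hessian falls back to the pseudo-inverse with a warning.  Rates and shapes
are reported on the natural scale with first-order delta-method SEs.

The reduced "non-informative LTF" model ties transition 5 to transition 1
at k = 1, which through the ratio constraint also forces
`lambda6 = lambda2`; it frees 23 parameters.  The likelihood-ratio statistic
`2 (ll_full - ll_reduced)` is referred to chi-square on 4 degrees of freedom
(boundary subtleties ignored, the conventional usage).  The pipeline helper
fits the reduced model first and starts the full fit from the embedded
reduced optimum so the nesting inequality holds by construction.

### Sensitivity protocol

`sensitivity_over_k` refits the full model over a k grid (default
{0.5, 1, 2}) and tabulates covariate coefficients by transition.  Robustness
is summarised by the **mean** relative shift across the 12 covariate
coefficients; a per-coefficient maximum is also available but diverges
whenever a coefficient is statistically indistinguishable from zero (a
percent change of a near-zero quantity carries no information), so the mean
is the headline metric.  On the packaged synthetic conditions the mean shift
is ~7 per cent while cumulative-incidence curves move by more than an order
of magnitude more — the qualitative signature of this class of model: only
intercept-like quantities (and hence absolute risk) absorb k, not hazard
ratios.

## Predictions

* Survival: `P(alive at t) = pi(x) A(CI,0,t) + (1-pi(x)) A(H,0,t)`,
  marginalised over the logistic screen state.
* Impairment cumulative incidence (sub-distribution, death as a competing
  risk by path construction, starting healthy):
  `F(t) = ∫_0^t [S_H(0,u) lambda2(u) + ∫_0^u S_H(0,w) lambda4(w) S_LTF(w,u)
  lambda6(u) dw] du` — counting entry into either impaired state, observed
  or latent post-LTF, which is exactly the quantity `k` governs.

## The synthetic-data generator

`semicr.simulate` draws complete latent trajectories by exact inversion of
each competing Weibull cumulative hazard on the global clock (baseline state
Bernoulli in the screen probability; earliest candidate exit wins), then
collapses them through an interview schedule: a subject attends an interview
iff latently H or CI at that time; the first missed interview defines the
LTF interval and ends observation; death times are always copied exactly.
The simulator is the package's Monte-Carlo oracle: pattern frequencies must
match the quadrature kernels, occupancies must match the matrix exponential
in the constant-hazard limit, and `observe ∘ sample` machine-checks that the
12-route enumeration is exhaustive.

Default conditions emulate a single-centre ageing cohort: ages
truncated-normal(75, 7) on [64, 103] years (median ≈ 74), 63% female,
interviews at 0, 2, 4, 7, 10 years, administrative end at 12 years, and a
logistic screen giving ~12% baseline impairment.  Death-transition
parameters use published cohort-scale magnitudes (e.g. H->D intercept 0.052,
shape 1.156, age 0.082, sex −0.602); the non-death intercepts and shapes are
chosen once to reproduce qualitative features of such studies — a
decreasing drop-out hazard (shape 0.75), a large early CI->drop-out rate
(intercept 0.35, shape 0.6) — and the simulator's LTF intervals use the
actual missed-interview time as the upper endpoint (real studies with
irregular schedules may have to approximate it; the reader accepts either).

What the generator does **not** emulate: misclassification of the cognitive
test, interview-time jitter, recovery CI->H, continuous cognitive scores,
and non-Markov (time-in-state) effects.  Passing oracle tests therefore
validate the likelihood/simulator pair under the model's own assumptions,
not the model's adequacy for any real cohort.

## Problem sizes in the test suite

Chosen as the package's own desk-scale study designs: parameter recovery
fits one n = 2000 cohort (every free parameter within 3 reported SEs of
truth); SE calibration, Wald coverage and bias use 20 replicates of n = 250;
the null-calibration check of the LRT uses 8 replicates of n = 600; the
Monte-Carlo oracle uses 2×10^5 trajectories (3 MC SE agreement per pattern);
curve checks use 10^5 trajectories.  Replicate-study fits start at the
generating values and use slightly relaxed stopping rules (gradient
tolerance 1e-3), which moves estimates by ~1e-3 — negligible against
standard errors ~0.1.

## Known limitations

* Weibull-only intensities; piecewise-constant or Gompertz baselines are out
  of scope (piecewise-constant would suit prediction better).
* The chi-square reference for the LRT ignores possible boundary effects,
  and is visibly anticonservative in small samples: with a few hundred
  subjects the freed post-LTF death block is informed by only a few dozen
  events and null statistics run well above chi-square(4) (simulation shows
  good calibration by n = 600 under the packaged conditions).  Treat small-n
  p-values near the threshold with caution.
* Weakly identified blocks (the LTF death hazard, the CI->CILTF shape) can
  yield non-positive-definite Hessians at small n; the pseudo-inverse
  fallback flags this.
* `k` is not estimable in principle; all absolute-risk statements inherit
  its choice, which is the point of the sensitivity protocol.
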