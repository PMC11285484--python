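# Methods

This note documents the models, estimators and numerical choices behind
`socdisc`, and what the synthetic-data generator does and does not
emulate.

## The task and its constants

The social discounting task presents, on every trial, a *selfish*
option (a variable amount A for the participant alone) against a
*generous* option (a fixed amount G for both the participant and a
named person at social distance D). The default `TaskDesign` uses
D ∈ {1, 2, 3, 5, 10, 20, 50, 100}, A ∈ {130, 150, …, 290} HKD,
G = 130 HKD — a full factorial of 72 trials — a 6 s response window, a
1 s inter-trial interval, a 0.3 s fast-guess floor, and compensation of
a 105 HKD flat fee plus 5% of the chosen amount(s) on one randomly
drawn trial (so the participant's own payout spans 111.5–119.5 HKD).

## Prosociality estimators

**Indifference points.** Per participant and distance, choice (selfish
= 1) is regressed on A by logistic regression; the indifference point
is the amount at which P(selfish) = 0.5, i.e. −intercept/slope. All-
selfish and all-generous responders are imputed half an increment
outside the amount range (120 and 300 HKD). A perfectly separated
mixed pattern (generous below some amount, selfish above) has a
divergent MLE; it resolves deterministically to the midpoint of the
separating gap, which is also the limit the penalized alternatives
approach and matches the spirit of the imputation rule. Estimates from
a converged logistic fit are clipped to [120, 300]. Skipped trials are
excluded.

**AUC.** Amounts forgone (indifference − 130) are clipped below at 0
and normalized by the theoretical maximum 170 HKD (not the
per-participant observed maximum, keeping the index comparable across
participants and exactly spanning [0, 1]); distances are normalized by
the largest design distance. An anchor at x = 0 carries the smallest-
distance y so that a flat ceiling profile integrates to exactly 1. The
raw −10 HKD forgone from the low imputation is retained in the profile
but contributes 0 to the AUC.

**Hyperbolic fit.** v = V/(1 + kD) is fitted to the amounts forgone by
ordinary least squares. V enters linearly given k, so V is profiled
out analytically and the search reduces to a 1-D bounded minimization
over ln k (grid scan of 60 log-spaced points in k ∈ [10⁻⁶, 10]
followed by bounded refinement). A flat profile carries no curvature
information; k is then pinned to the lower bound and the fit flagged
`k_at_lower_bound`.

**Softmax MLE.** Trial-level likelihood
P(selfish) = 1/(1 + e^{−σ(A − (130 + V/(1+kD)))}), optimized over
(ln k, V, ln σ) with L-BFGS-B from a deterministic 3×3×3 start grid
(k ∈ {0.01, 0.1, 1}, V ∈ {50, 170, 400}, σ ∈ {0.01, 0.05, 0.5});
bounds k, σ ∈ [10⁻⁶, 10], V ∈ [0, 1000]. Skipped trials and trials
faster than 0.3 s are removed first and at least 20 must remain. With
σ → 0 the likelihood is flat in (k, V); fits with σ̂ < 5·10⁻³ (value
differences of ~100 HKD moving the choice probability by only a few
points) are flagged `weakly_identified`. k is reported with ln k, the scale on which group
analyses run.

## Drift-diffusion model

The Wiener first-passage density (boundary separation α, relative
start β, drift δ, non-decision time τ, unit diffusion) is evaluated
through the zero-drift unit-boundary kernel with the small-time and
large-time series, switching per time point to whichever needs fewer
terms at truncation error 10⁻⁷ (capped at 64 terms); drift and scale
enter by exponential tilting, and the upper boundary uses the
reflection identity f_upper(t; δ, β) = f_lower(t; −δ, 1−β). The upper
boundary maps to the selfish choice (a documented, configurable
convention — the mapping is shared by the generator and the fitter).

**Hierarchy.** Participant-level parameters live on transformed
scales: ln α, logit β, δ untransformed, and
τ = 0.1 + logit⁻¹(z)·(0.95·minRT − 0.1), where minRT is that
participant's fastest retained RT — this enforces the 0.1 s lower
bound and keeps τ below the fastest response. On each transformed
scale, participant values are Normal(cell mean, subject SD) with the
cell mean given by μ + β_sex·sex + β_cond·cond + β_int·sex·cond
(female = 0/male = 1, control = 0/androstadienone = 1). All 16
coefficients have standard-normal priors; the four subject SDs have
half-normal(1) priors.

**Sampler.** An adaptive Metropolis-within-Gibbs scheme:

- subject-level parameters move by joint 4-D random-walk proposals
  whose covariance is learned per participant during warm-up
  (adaptive-Metropolis moments, scaled 2.38²/4, per-subject step
  factor tuned to ≈23% acceptance); an initial warm-up segment uses
  componentwise proposals while moments accrue;
- the group coefficients are drawn from their exact conjugate normal
  conditionals;
- the subject SDs are drawn by a stepping-out slice sampler on the log
  scale;
- translation moves shift a coefficient together with the subjects it
  governs (leaving residuals unchanged), and scale moves rescale a
  parameter's subject spread jointly with its SD — these traverse the
  long ridges of the centered parameterization.

The default test-scale configuration is 4 chains × 1000 iterations
(half warm-up); the study-scale configuration of 4 × 4000 is a flag
away. Convergence is assessed by the rank-normalized split R-hat
(maximum of the bulk and folded variants) on all 20 group-level
scalars; any value ≥ 1.01 flags the fit as unconverged rather than
failing silently. A group difference is "credible" when the 95%
highest-density interval (narrowest interval holding 95% of the
draws) of its coefficient excludes zero.

The non-decision-time block mixes the slowest: τ's scaled-logit
saturates when a participant's τ approaches its minRT-based cap, and
the flat likelihood direction makes the τ coefficients' effective
sample size roughly 3–5× smaller than the other blocks'. At the
test-scale configuration a fit can therefore be flagged unconverged on
a τ scalar while every substantive coefficient has mixed; the
study-scale configuration resolves this.

## Design statistics

Two-way between-subject ANOVA uses Type II sums of squares (the
study's cells are unbalanced), with generalized η² =
SS_effect/(SS_effect + SS_residual), which coincides with partial η²
in a purely between-subject design. The one-sample t returns Cohen's
d = t/√n. A-priori power for a fixed-effects ANOVA contrast is
P(F′ > F_crit) with F′ noncentral F(df₁, N − k, λ = f²N); the required
N is the smallest integer meeting the target power. With the rounded
f = 0.241 the exact power at N = 137 is 0.7997, so the strict rule
returns 138; any unrounded effect size above 0.2412 returns 137.

## Synthetic-data generator

Cohorts are 2 sex × 2 condition cells. Central parameter values per
cell default to k = 0.15, V = 170 HKD, σ = 0.05/HKD (a typical
moderately discounting, moderately noisy chooser) and α = 1.5,
β = 0.5, δ = 0.3, τ = 0.35 s (unbiased accumulation mildly drifting
toward the selfish boundary, median RT near 0.9 s). Between-
participant dispersion is log-normal for positive parameters
(SD 0.2–0.5 on the log scale), logit-normal for β, normal for δ.
Contamination defaults: 3% fast guesses (uniform RT below the 0.3 s
floor, random choice) and 2% skipped trials (unanswered at both the
first presentation and the single end-of-block re-presentation; they
appear as choice = `skipped` with empty RT).

Two generative modes mirror the fitted models: softmax mode draws
choices from the discounting + softmax rule (with placeholder
lognormal RTs, since that model is silent about time), and diffusion
mode draws choices and RTs jointly from the first-passage process.
Drift is constant per participant (not value-scaled), matching the
fitted model. The Euler-Maruyama simulator (1 ms step) applies the
exact Brownian-bridge crossing probability between steps, reducing
first-passage bias to O(dt); diffusion RTs beyond the 6 s window
become skipped trials.

What the generator does not emulate: value-dependent drift (so
diffusion-mode choices are independent of the amounts on offer and
discounting estimators should be validated on softmax-mode data),
distance-blocked sequential effects, learning or fatigue across
trials, RT–choice dependence in softmax mode, and any olfactory or
physiological mechanism. Passing recovery tests therefore show the
estimators are correct under the stated model, not that the model is
true of real behaviour.

## Problem sizes used in the test suite

Recovery and calibration suites run at desk scale: 100 simulated
participants for MLE recovery; 80,000 Euler trials per parameter set
for the density oracle; a 20-per-cell null cohort at 4 × 1000 for the
HDI null check; 50 two-per-cell micro-cohorts (24-trial sessions,
2 × 300 iterations) for HDI calibration; and a 3-per-cell cohort at
the study-scale 4 × 4000 for the convergence contract. These sizes
were chosen so the full suite runs in minutes while keeping Monte-
Carlo error well inside each assertion's tolerance.

## Known limitations

- The sampler is random-walk based; posterior geometry with strongly
  saturated τ transforms mixes slowly (flagged, as described above).
  A gradient-based sampler would remove this caveat.
- `fit_hyperbolic` assumes homoscedastic Gaussian noise on amounts
  forgone; the loss is a design choice, as is every optimizer setting
  in the MLE route.
- The AUC normalization (theoretical maximum, −10 clipped to 0, x = 0
  anchor) is one of several defensible trapezoid conventions; the
  choices are documented above and the raw values are always
  retained.
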