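# socdisc

Analysis toolkit for **social discounting**: the decline of generosity
with social distance, measured by choices between a selfish option (a
variable amount A for oneself) and a generous option (a fixed 130 HKD
for both oneself and a person at social distance D). The package is
aimed at decision scientists who want a tested, reproducible pipeline
for this task — from raw trial tables (or simulated cohorts with known
ground truth) to the three standard prosociality estimates, a
hierarchical Bayesian drift-diffusion model, and the surrounding
design statistics.

## What it computes

**Model-free AUC.** Per participant and distance, logistic regression
of choice on A yields the indifference point (P(selfish) = 0.5);
one-sided responders are imputed half an increment outside the amount
range (120/300 HKD). Amounts forgone v = indifference − 130 are
normalized by their theoretical maximum (170 HKD) and integrated over
normalized distance by the trapezoid rule: AUC ∈ [0, 1], 1 = no
discounting.

**Hyperbolic discounting.** v = V/(1 + kD), with V the generosity
intercept (HKD forgone at D = 0) and k the discount rate — fitted by
least squares to the amounts forgone, and, independently, by
trial-level maximum likelihood under the softmax rule
P(selfish) = 1/(1 + e^{−σ(A − (130 + V/(1+kD)))}), after removing
trials faster than 300 ms.

**Hierarchical DDM.** Choices and response times jointly modelled by a
Wiener diffusion (boundary separation α, start bias β, drift δ,
non-decision time τ); each parameter's participant-level values are
regressed on sex, condition and their interaction
(θ = μ + β_sex·sex + β_cond·cond + β_int·sex×cond, standard-normal
priors) and sampled by MCMC with rank-normalized split R-hat
diagnostics (< 1.01) and 95% highest-density-interval decisions.

**Design statistics.** Two-way between-subject ANOVA (Type II, with
generalized η²), one-sample t with Cohen's d, and a-priori
power/sample size via the noncentral F distribution (λ = f²N).

A synthetic-data generator produces full 2 sex × 2 condition cohorts
with known discounting and diffusion parameters, fast-guess and
skipped-trial contamination included, so every estimator has a
recovery test. See `docs/methods.md` for model details and numerical
choices.

## Worked example

```python
import numpy as np
from socdisc import (TaskDesign, default_truth, simulate_cohort,
                     profile_cohort, fit_mle_cohort, two_way_anova,
                     PowerSpec, required_n)

design = TaskDesign()
truth = default_truth(n_per_cell=10, seed=7, fast_guess_rate=0.03,
                      skip_rate=0.02, with_ddm=False)   # softmax mode
cohort = simulate_cohort(truth, design)          # 40 participants x 72 trials

profiles, auc = profile_cohort(cohort)           # model-free estimates
print(round(auc["auc"].mean(), 3), round(auc["auc"].std(), 3))
# 0.229 0.128

mle = fit_mle_cohort(cohort)                     # softmax MLE per participant
print(round(float(np.nanmedian(mle["k"])), 3),
      round(float(np.nanmedian(mle["V"])), 1))
# 0.136 172.1        (generating cell medians: k = 0.15, V = 170)

res = two_way_anova(auc["auc"], auc["sex"], auc["condition"],
                    factor_a="sex", factor_b="condition")
print({k: round(v, 3) for k, v
       in res.table.loc["sex:condition", ["F", "p"]].items()})
# {'F': 3.668, 'p': 0.063}   (null cohort: no credible interaction)

spec = PowerSpec(effect_size_f=0.2415, alpha=0.05,
                 target_power=0.80, numerator_df=1, n_groups=4)
print(required_n(spec))
# 137                        (a-priori N for a 4-group ANOVA contrast)
```

The AUC mean ≈ 0.23 says this simulated cohort forgoes, averaged over
distances, about a quarter of the maximal amount — a moderately
discounting sample; the MLE medians recover the generating k and V;
the interaction F-test stays non-significant because no sex ×
condition effect was simulated; and 137 participants suffice for 80%
power at Cohen's f = 0.2415. (Diffusion-mode cohorts, used for DDM
fitting, generate choices from a constant-drift process that ignores
value differences, so the discounting estimators are demonstrated on
a softmax-mode cohort.)

The same stages are available from the shell:

```bash
socdisc simulate --seed 7 --out trials.csv
socdisc fit-auc --in trials.csv --out auc.csv
socdisc fit-mle --in trials.csv --rt-floor 0.3 --out mle.csv
socdisc fit-ddm --in trials.csv --chains 4 --iter 4000 --seed 7 --out ddm.json
socdisc anova --in auc.csv --response auc --factors sex,condition
socdisc power --f 0.241 --alpha 0.05 --power 0.80 --df1 1 --groups 4
socdisc report --config pipeline.yaml           # full pipeline + report.json
```

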