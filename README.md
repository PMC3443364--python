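# semicr

Semi-competing-risks multi-state modelling of interval-censored illness data
with exact death times and **informative loss to follow-up**.

## The problem

Longitudinal ageing cohorts observe a non-terminal condition — here
cognitive impairment (CI), dichotomised from a screening test — only at
scheduled interviews, sometimes years apart, while death times are exact
thanks to mortality-registry flagging.  Two complications break standard
survival tools:

* **semi-competing risks** — death censors impairment but not vice versa,
  and frailer people are likelier to experience both;
* **informative drop-out** — participants who stop attending interviews
  (loss to follow-up, LTF) may do so *because* they are becoming impaired,
  so treating drop-out as ignorable censoring biases the impairment process.

`semicr` models both explicitly with a five-state continuous-time model
(H, CI, LTF, CI(LTF), D; eight transitions) with Weibull
proportional-hazards intensities on the time-since-entry clock,

λ_m(t | x) = τ_m α_m t^{α_m−1} exp(x′β_m),   x = (centred age, female),

a logistic model for impairment at the prevalence screen, and two
identifiability constraints: λ₇ = λ₃ (death of the impaired does not depend
on drop-out status) and λ₁λ₆ = k λ₂λ₅, where **k is a fixed sensitivity
constant** — the data carry no information about it, so analyses are
repeated over a k grid.  The likelihood is a product of the probabilities of
the 12 observable routes a record can take, each summing over all latent
trajectories between observations (nested Gauss–Legendre quadrature).  The
package provides maximum-likelihood fitting with Hessian standard errors, a
4-df likelihood-ratio test for informative LTF (tying λ₅ = λ₁, hence
λ₆ = λ₂, at k = 1), model-based survival and impairment
cumulative-incidence curves, and an exact latent-trajectory simulator that
doubles as a Monte-Carlo oracle for every probability the likelihood
computes.

Audience: biostatisticians analysing panel/interview cohort data with
terminal events and suspect drop-out, and methodologists who want a tested
reference implementation of this model class.

## Worked example

```python
import numpy as np
from semicr import Covariates, fit, FitOptions, survival_curve, ci_cumulative_incidence
from semicr.inference import test_informative_ltf
from semicr.simulate import default_params, simulate_cohort

truth = default_params()                       # illustrative cohort-scale parameters
sim = simulate_cohort(truth, n=1000, seed=8001)

opts = FitOptions(quad_nodes=8, two_year_rule=False, compute_se=False)
full, reduced, lrt = test_informative_ltf(sim.records, options=opts)
print(f"LRT for informative LTF: stat={lrt.statistic:.1f}, df={lrt.df}, p={lrt.p_value:.2g}")

x = Covariates(0.0, 1)                          # mean study age, female
grid = np.array([0.0, 5.0, 10.0])
print("P(alive):", survival_curve(full.params, x, grid).round(3))
print("P(impaired by t):", ci_cumulative_incidence(full.params, x, grid).round(3))
```

Output from this exact run:

```
LRT for informative LTF: stat=27.7, df=4, p=1.4e-05
P(alive): [1.    0.76  0.463]
P(impaired by t): [0.    0.155 0.331]
```

The cohort was generated with genuinely different pre- and post-drop-out
hazards, so the likelihood-ratio statistic (27.7 on 4 degrees of freedom)
rejects non-informative LTF decisively; a mean-age female has an estimated
46% chance of being alive and a 33% chance of having become impaired
(including latently, after drop-out) by year 10.  Refitting over
k ∈ {0.5, 1, 2} (`semicr.inference.sensitivity_over_k`) leaves covariate
coefficients nearly unchanged (mean relative shift ≈ 7%) while the
cumulative-incidence curves move by up to ~0.17 — absolute risk inherits
the unidentifiable k, hazard ratios do not.

There is also a CLI:

```bash
semicr simulate --n 1000 --seed 1 --out cohort.csv
semicr fit --data cohort.csv --k 1 --out fit.json
semicr lrt --data cohort.csv
semicr sensitivity --data cohort.csv --k-grid 0.5,1,2 --out tableIV.csv
semicr curves --fit-json 1.0 fit.json --out curves.csv
semicr validate --data cohort.csv
```

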