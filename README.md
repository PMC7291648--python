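# msfrail

Semi-Markov multi-state survival modelling with a **nonparametric discrete
shared frailty** over healthcare providers.

## The problem

Chronically ill patients — heart failure is the motivating case — cycle
repeatedly between hospital and home, and may die in either state.  Profiling
the hospitals that treat them on a single binary outcome (say, 30-day
mortality) throws away most of this history.  `msfrail` models the whole
pathway as a three-state, clock-reset (semi-Markov) process —

```
        l=1: discharge
  [in hospital]  ⇄  [out of hospital]
        l=3: readmission
       l=2 ↘        ↙ l=4
            [dead]
```

— and asks, for each of the four transitions separately, whether providers
fall into a small number of *latent populations* that shift the transition
hazard up or down after adjusting for patient case mix.

## The model

For subject `i` in provider `j`, conditional on provider `j` belonging to
latent population `k` of transition `l`, the hazard at time `t` since entry
into the origin state is

```
λ^l(t | X_ij, k) = λ₀^l(t) · w_k^l · exp(β^lᵀ X_ij)
```

with `λ₀^l` an unspecified baseline hazard, `β^l` the case-mix coefficients
(age, sex, ≥3 comorbidities, number of procedures) and `w^l = (w₁,…,w_K)` a
discrete frailty shared by all providers of the same population, with mixing
proportions `π^l`.  Equivalently each transition is a K-component mixture of
proportional-hazards models.  Estimation is by EM with a profiled Breslow
baseline; the number of populations `K^l` is chosen per transition by BIC (or
AIC) in an outer grid loop; providers are assigned to populations by Bayes
rule.  Frailties are reported as ratios `w_k / w₁`, ascending from 1.  The
cross-transition behaviour of providers is summarized by an assignment matrix
`A` (providers × transitions) and the counts of each latent-population
pattern.  Cumulative incidence functions per population and covariate profile
account for the competing transition out of each origin state.

Because registry data of this kind cannot be redistributed, the package ships
a simulator that generates registry-like hierarchical cohorts (providers,
repeated admissions, competing events, five-year administrative censoring)
with known ground truth, which the test suite uses throughout.

## Worked example

```python
import numpy as np
from msfrail import (recovery_scenario, simulate_cohort,
                     build_transition_datasets, DiscreteFrailtyCoxPH)

# a cohort of 60 providers whose discharge hazards come from three
# latent populations with frailty ratios (1, 2, 4)
scen = recovery_scenario(J=60, provider_size_range=(20, 80))
cohort = simulate_cohort(scen, seed=7)

ds = build_transition_datasets(cohort.episodes)[1]   # admission -> discharge
model = DiscreteFrailtyCoxPH(n_populations=3, random_state=0)
model.fit(ds.frame[["age", "sex", "comorb3", "n_procedures"]],
          (ds.time, ds.event), groups=ds.groups)

print(np.round(model.frailty_ratios_, 2))        # [1.   2.2  4.4]
print(np.round(model.mixing_proportions_, 2))    # [0.2  0.51 0.29]
print(model.hazard_ratios().round(4))
```

prints (3,176 patients, 4,131 admissions):

```
frailty ratios:      [1.   2.2  4.4]
mixing proportions:  [0.2  0.51 0.29]
   covariate    coef     hr     se
         age  0.0224 1.0226 0.0016
         sex  0.1778 1.1946 0.0403
     comorb3  0.4092 1.5056 0.0510
n_procedures -0.2923 0.7466 0.0251
```

The three generating frailty ratios (1, 2, 4) are recovered within sampling
error, the hazard ratios match the generating coefficients
`β = (0.02, 0.2, 0.4, −0.3)`, and the Bayes-rule provider assignments agree
with the simulated labels (adjusted Rand index 0.9).  `FrailtyCoxSelector`
adds the BIC/AIC grid over K, and `MultiStateFrailtyModel` runs all four
transitions and builds the assignment and pattern tables.

A command line covers the same pipeline end to end:

```sh
msfrail simulate --seed 7 --out cohort.csv
msfrail fit --input cohort.csv --out-dir results/ --k-max 4 --seed 1
```

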