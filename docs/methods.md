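# Methods

## Model

The patient pathway is a three-state process — alive in hospital, alive out
of hospital, dead (absorbing) — with four transitions: admission→discharge
(l=1), admission→in-hospital death (l=2), discharge→readmission (l=3) and
discharge→out-of-hospital death (l=4).  The process is semi-Markov with clock
reset: every hazard is a function of time since entry into the current state,
in days.  Within each origin state the two outgoing transitions are competing
risks; the occurrence of one censors the other, and administrative censoring
at end of follow-up (default 1,826 days = 5 years including a leap day) caps
both.

For subject i of provider j, conditional on provider j belonging to latent
population k of transition l,

    λ^l(t | X_ij, k) = λ₀^l(t) · w_k^l · exp(β^lᵀ X_ij),

where X contains age (years at first admission), sex (male = 1, reference
female), an indicator of ≥3 comorbidities, and the number of procedures
(0–5).  The frailty W^l is a discrete random variable with K^l support points
w₁ ≤ … ≤ w_K and masses π^l; all providers of a population share one value.
Each transition can equally be read as a K-component mixture of proportional
hazards models with common β and baseline.  Transitions are fitted
independently: no correlation between a provider's frailties across
transitions is modelled (a deliberate scope boundary; a joint frailty across
transitions would require a different estimation strategy).

### Identifiability

Multiplying all w by c and dividing the baseline by c leaves the likelihood
unchanged, so fits are reported with populations sorted by w ascending and
w₁ ≡ 1, the scale folded into the baseline.  Frailty ratios w_k/w₁ therefore
start at 1, and the baseline hazard is the hazard of the lowest-frailty
population at the reference covariate profile.

## Estimation

Parameters (λ₀, β, w, π) at fixed K are estimated by EM on the observed-data
log-likelihood

    ℓ = Σ_j log Σ_k π_k exp(ℓ_jk),
    ℓ_jk = Σ_i [ δ_ij (log h(t_ij) + log w_k + β᾿X_ij) − w_k e^{β᾿X_ij} Λ₀(t_ij) ],

with h the baseline increments at the distinct observed event times and Λ₀
their running sum (computed with log-sum-exp over components).

- **E-step.**  Posterior membership α_jk ∝ π_k exp(ℓ_jk) per provider (Bayes
  rule); the final assignment is the row-wise argmax.
- **M-step.**  π_k is the posterior mean.  β and the baseline are updated
  *jointly*: profiling h out of the expected complete-data log-likelihood
  leaves a weighted Breslow partial likelihood with per-row weight
  m_i = Σ_k α_{j(i)k} w_k, maximized by Newton's method with step halving;
  the Breslow increments h_r = d_r / Σ_{risk set} m_i e^{β᾿X_i} are evaluated
  at the resulting β.  w_k then has the closed form
  (Σ_j α_jk D_j) / (Σ_j α_jk Σ_i e^{β᾿X_i} Λ₀(t_i)).  The (β,h)/w cycle runs
  twice per M-step.  Every block maximizes the expected complete-data
  log-likelihood in its own coordinates, so the observed log-likelihood is
  non-decreasing; the fitter asserts this at every iteration.  Profiling the
  baseline inside the β update (rather than alternating β against a frozen
  baseline) is what makes K=1 collapse to the exact Cox partial-likelihood
  solution in a couple of EM iterations instead of converging linearly.
- **Ties** use the Breslow approximation — the only choice consistent with
  the profiled baseline above.  The simulator produces continuous times, so
  ties are rare there, but the fitter handles them.
- **Initialization.**  A null (K=1) fit supplies β and the baseline; per
  restart, providers are partitioned at random into K groups (or into K
  crude-rate quantile blocks for the deterministic variant) and w starts at
  the group-wise observed/expected event ratios, π uniform.  Five restarts by
  default, best final log-likelihood wins; all randomness flows from one
  seed.  K=1 is deterministic and runs once.
- **Convergence** when the relative change in observed log-likelihood falls
  below 1e-6 (default), capped at 500 iterations.  A mixing proportion below
  1e-8 flags the run as degenerate; restarts absorb such collapses.
- **Standard errors** of the hazard ratios come from the weighted
  partial-likelihood information at convergence with the posteriors treated
  as fixed case weights, then the delta method.  Classification uncertainty
  in the frailties is not propagated, so these SEs understate the true
  variability; a Louis-type correction is out of scope and the limitation is
  deliberate and documented.

## Choosing K

K is not identified by likelihood maximization, so an outer loop fits
K = 1..k_max and compares information criteria with

    d = p + (K−1) frailty + (K−1) mixing parameters,

the nonparametric baseline being profiled out and not counted.  BIC uses the
number of subjects (rows) in the transition dataset as n; events or providers
are defensible alternatives and this is a convention, not an estimate.  A
log-likelihood that *decreases* when K grows signals a poor local optimum;
the selector refits that K once with fresh restarts and keeps the better
result.  A support-size heuristic is also available: grow K until the fit
degenerates — some π_k < 1e-3, or two support points within 1e-2 on the log-w
scale — and return the last non-degenerate K.  Both thresholds are this
package's choices; in line with how such support-size rules behave, it tends
to return at least the BIC choice.

## Cumulative incidence

For transition l, population k and profile X, the discrete hazard increments
are λ̂(t_r) = h_r w_k e^{β᾿X} and

    Î(t) = Σ_{r: t_r ≤ t} λ̂(t_r) · Ŝ(t_{r−1}),

where Ŝ is computed **model-based** as the all-cause survivor of the origin
state, Ŝ(t_r) = Π_{s ≤ r} (1 − Σ_{l′ out of origin} λ̂^{l′}(t_s)), on the
union of the event-time grids involved.  This keeps the CIF self-contained
(one curve per population and profile) and respects competing risks; the
alternative — an empirical Kaplan-Meier survivor per provider — would mix
model-based and empirical quantities and is not used.  The competing
transition's population defaults to its modal (highest-π) population when not
specified.  Increments above 1 (possible in sparse risk sets) are clipped
with a warning.  With no competing hazard the curve reduces to
1 − Π(1 − λ̂), which converges to 1 − e^{−Λ(t)} as the grid refines — one of
the test suite's checks at n = 10,000.

## Pattern tables

The assignment matrix A holds each provider's Bayes-rule label for each
transition.  The configuration matrix C enumerates all Π_l K^l label
combinations (lexicographic); the pattern table counts each row of C in A and
reports the share of providers to one decimal, sorted by count.  Counts sum
to J by construction.  A transition with no events (possible in small
synthetic cohorts) is flagged with K=0 and a constant assignment column.

## Simulator

The generator emulates the structure of a regional heart-failure admission
registry: by default J = 140 providers with 20–400 patients each (the
≥20-patient floor mirrors the provider filter used in estimation), up to 5
admissions per patient, and 5-year administrative censoring.  Covariates at
first admission: age ~ truncated Normal(77, 12) on [40, 100]; 51% female
(sex codes male = 1); ≥3 comorbidities ~ Bernoulli(0.45); procedures ~
Poisson(0.25) truncated to {0..5}.  Per transition and provider a latent
label is drawn from Categorical(π); latent transition times are drawn by
inverse transform from Λ₀(t)·w·e^{β᾿X} = −log U with Weibull or
piecewise-exponential baselines, and within each state the minimum of the two
competing latent times wins.  Default baselines are exponential with scales
calibrated so the population-typical daily rates at the mean covariate
profile are 0.0635 (discharge), 0.0079 (in-hospital death), 0.00027
(readmission) and 0.00035 (out-of-hospital death) — i.e. mean stay around two
weeks, roughly 11% in-hospital deaths per admission, and about two thirds of
discharged patients readmitted or dead within five years.  Default regression
effects are plausible log hazard ratios of the same sign and order as
published heart-failure case-mix effects.  These defaults are realistic
magnitudes, not calibration claims.

Two boundary conventions keep the generated tables consistent with
administrative data: a hospital stay still in progress at the censoring date
is observed to its end (admission records are complete) and the patient's
follow-up ends there, so the cohort-accounting identity
admitted = discharged + in-hospital deaths holds exactly; and a patient
reaching the maximum admission count has follow-up truncated at that
discharge.  Times are continuous (fractional days).

What the simulator does **not** emulate: seasonal or calendar-time effects,
time-varying covariates, provider-level covariates, correlation of a
provider's frailties across transitions, coding errors and transfers between
institutions.  Passing recovery tests on these cohorts therefore shows that
the estimator recovers the generating mechanism of the model class — not
that real registry data satisfy that mechanism.

## Episode-table conventions

Dates are consumed either as ISO-8601 strings (converted to day offsets from
the earliest admission) or directly as numeric day offsets; all model time
units are days.  Zero-length spells (same-day admission and discharge, or
discharge exactly at the follow-up end) are recoded to 0.5 days so that all
transition times are strictly positive.  A readmission on the calendar day of
discharge is merged into the previous episode as one continuous stay and
counted in the validation diagnostics.  An out-of-hospital death is attributed
to transition 4 with the last discharge as the time origin.  Patients treated
at more than one institution are outside the cohort definition and rejected
with a structured error.

## Problem sizes in tests

The recovery checks run 20 replicates of the full-scale scenario (J = 140,
provider sizes 20–400, K = 3, frailty ratios 1:2:4, β = (0.02, 0.2, 0.4,
−0.3)) and require BIC to select K = 3 in at least 80% of replicates, median
frailty-ratio error within 10%, median adjusted Rand index above 0.9 and
median coefficient error below 0.05.  Oracle comparisons use scikit-survival's
Breslow-tie Cox fit (K=1 equivalence, 1e-6 relative) and direct mixture
enumeration on ≤5-provider instances (1e-10 absolute).  Distributional checks
(Weibull sampling, competing-risk fractions, CIF exponential limit) use
10,000 draws with tolerances of three binomial standard errors or ~3/√n.
Smaller cohorts (10–100 providers of 10–80 patients) are used for structural
and property tests; these sizes are the package's own testing choices.

## Known limitations

- SEs ignore classification uncertainty (see above).
- BIC's n convention (subjects) affects selected K in borderline cases.
- The EM can hit local optima at K larger than the truth; restarts and the
  decrease-triggered refit mitigate but do not eliminate this.
- No proportional-hazards diagnostics are provided; the model assumes PH for
  both covariates and frailties.
- CIF curves are model-based; no empirical (per-provider Kaplan-Meier)
  variant is implemented.
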