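# idmrisk

Age-specific prevalence of a chronic disease in the classical illness-death
model (Healthy → Ill → Dead, Healthy → Dead), when the transition hazards
depend on a scalar risk factor whose population distribution an intervention
may shift.  The package implements the same question two ways and compares
them:

* **DES** — an individual-level discrete-event simulation: each person in a
  closed birth cohort gets a lifelong risk-factor value and competing-risk
  failure times (disease onset vs disease-free death, then post-onset death)
  sampled by cumulative-hazard inversion.
* **ERM** — the *effective-rate method*: replace each covariate-dependent
  hazard by its expectation over the risk-factor density,
  λ\*(a) = ∫ λ(a, Z) f(Z) dZ (and likewise μ0\*, with μ1\* = HR·μ0\*), and
  solve the cohort prevalence ODE

  dπ/da = (1 − π) (λ\* − π (μ1\* − μ0\*)),   π(30) = 0,

  the reduction of the age-structured prevalence PDE
  (∂ₜ + ∂ₐ)π = (1 − π)(λ − π(μ1 − μ0)) along a birth cohort's
  characteristic line.  The ERM needs only aggregate rates — no
  individual-level data — and its cost is independent of cohort size.

The shipped default parameterisation is type-2 diabetes with BMI as the risk
factor: incidence ε·exp(αa² + βa + γ + δZ), disease-free mortality
exp(ξ·|Z − z0| + ϑ + νa) (Gompertz–Makeham with a j-shaped BMI term), hazard
ratio HR = 2 for the diseased, and BMI following a beta(3, 8) law rescaled
to [17, 47] (base case) vs beta(2.8, 8) (population-wide lifestyle
intervention).

## Worked example

```
$ idm run --out results/
ERM base_case: prevalence at age 80 = 64.0%
ERM intervention: prevalence at age 80 = 62.4%
DES base_case: prevalence at age 80 = 60.6%
DES intervention: prevalence at age 80 = 59.2%
DES base_case: overall person-time prevalence = 13.37%
DES intervention: overall person-time prevalence = 13.06%
ERM base_case: overall survival-weighted prevalence = 13.62%
ERM intervention: overall survival-weighted prevalence = 13.29%
intervention reduces overall prevalence by 0.31 pp
```

Reading the output: under the default hazards an 80-year-old has the disease
with probability ≈64% by the analytical route and ≈60.6% in the simulated
cohort of 10000 (the gap is the ERM's survivor-selection bias, see
`docs/methods.md`); shifting the BMI distribution slightly downward lowers
the cohort's lifetime person-time prevalence by ≈0.31 percentage points.
Because both scenario cohorts share the root seed and every per-individual
substream (common random numbers), that small paired difference is estimated
far more precisely than either level.

`results/` then contains `prevalence_curves.csv`
(`age,prevalence,ci_lower,ci_upper,method,scenario`, 95% Wilson intervals
for the simulation), `overall_summary.csv` and a `run_metadata.json` log.
`idm defaults` prints the full default parameterisation as YAML; a file with
the same structure (top-level `n`, `seed`, `age_cap`, `ode_start_age`,
`ode_initial_prevalence` and per-scenario `base_case:` / `intervention:`
blocks with the hazard symbols and `phi`, `psi`, `support_lower`,
`support_upper`) can be passed via `idm run --config`.

The same functionality is available as a library:

```python
import numpy as np
from idmrisk import (RateParameters, ScaledBetaDistribution,
                     effective_rates_from_model, solve_prevalence_ode,
                     simulate_cohort, estimate_prevalence)

rates = effective_rates_from_model(RateParameters(), ScaledBetaDistribution.base_case())
erm = solve_prevalence_ode(rates, 30, 110, 0.0)          # pi(80) = 0.6402
cohort = simulate_cohort(RateParameters(), ScaledBetaDistribution.base_case(),
                         n=10_000, seed=1980)
des = estimate_prevalence(cohort, np.arange(30.0, 111.0))
```

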