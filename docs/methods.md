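# Methods

## Model

The illness-death model has states Healthy (H), Ill (I), Dead (D) and three
transition hazards: incidence λ (H→I), disease-free mortality μ0 (H→D) and
mortality of the diseased μ1 (I→D).  There is no remission (I→H) and the
cohort is closed (no migration or replenishment).  The prevalence π(t, a) —
the fraction of those *alive* at age a who are ill — satisfies the
transport-type PDE

    (∂/∂t + ∂/∂a) π = (1 − π) (λ − π (μ1 − μ0)),

a relative of the von Foerster equation of age-structured population
dynamics.  For a single birth cohort calendar time is redundant and the PDE
reduces, exactly, to an ODE in age along the characteristic t − a = birth
year.  `solve_prevalence_pde` integrates along exactly that characteristic
and is therefore bit-identical to `solve_prevalence_ode` for time-constant
rates; it exists so that calendar-time rate modifications can be expressed
naturally.

All hazards depend on age a and a scalar risk factor Z (BMI, kg/m²), fixed
for life per individual:

    λ(a, Z)  = ε · exp(α a² + β a + γ + δ Z)
    μ0(a, Z) = exp(ξ |Z − z0| + ϑ + ν a)
    μ1(a, Z) = HR · μ0(a, Z)

The incidence is exponential-parabolic in age (vertex at −β/2α = 104.5
years with the defaults, i.e. increasing throughout the modelled range) and
log-linear in BMI; disease-free mortality is Gompertz–Makeham in age with a
j-shaped BMI penalty minimised at the reference value z0.  The hazards are
pure functions of continuous age and unrestricted real Z — the support
restriction lives in the risk-factor distribution.

### Parameters (defaults)

| symbol | default | units | role |
|---|---|---|---|
| ε | 0.014 | 1/year | incidence scale |
| α | −0.001 | 1/year² | quadratic age coefficient of incidence |
| β | 0.209 | 1/year | linear age coefficient of incidence |
| γ | −11.112 | — | incidence intercept |
| δ | 0.1 | per BMI unit | log-linear BMI effect on incidence |
| ξ | 0.02 | per BMI unit | j-shaped BMI effect on mortality |
| ϑ | −10.948 | — | Gompertz–Makeham intercept |
| ν | 0.095 | 1/year | Gompertz age slope |
| z0 | 23.75 | kg/m² | mortality-minimising BMI |
| HR | 2 | — | mortality hazard ratio ill vs healthy |

The risk factor follows a beta(ϕ, ψ) law transported affinely to [17, 47]
BMI units: base case ϕ = 3, ψ = 8 (mean 25.18, mode 23.67, right-skewed);
intervention ϕ = 2.8, ψ = 8 — a small population-wide downward shift such
as a realistic lifestyle campaign could achieve.  Cohort size n = 10000,
censoring age 110 (survival beyond it is negligible under the defaults),
initial condition π(30) = 0 for the analytical route (onset before 30 is
rare for the modelled disease).

## Effective-rate method

`effective_rate` averages a hazard over the risk-factor density at each
age by fixed 128-node Gauss–Legendre quadrature on the support.  The
integrands (polynomial beta density × smooth hazard) make this accurate to
far below the 1e−8 contract, verified in the tests against adaptive
Gauss–Kronrod quadrature and a closed-form exponential moment (Kummer's
confluent hypergeometric function).  No separability of the hazard is
assumed.  Caveat: a fixed-order rule cannot resolve a density concentrated
on a scale finer than its node spacing (~0.4 BMI units mid-support); for
near-degenerate laws evaluate the hazard at the atom instead.  μ1\* is
formed as HR·μ0\* so the hazard-ratio identity holds exactly in floating
point.

The prevalence ODE is integrated by classical fixed-step RK4, step 0.01
years, rates evaluated on the half-step grid.  A fixed step makes runs
bit-reproducible and the PDE/ODE reduction exact; halving the step changes
π(80) by ~1e−13 (tested against a 1e−8 bound), so discretisation error is
irrelevant next to every other error source.  The solution is asserted — not
clipped — to stay in [0, 1]: the dynamics cannot leave the unit interval
from a valid start, so a violation signals invalid rates.  Prevalence below
the ODE start age is reported as 0 by convention.

The ERM uses the *birth-cohort* density f(Z) at every age, which is what
makes it an aggregate-data method.  Because mortality differs across Z
(and, indirectly, because high-Z individuals become ill and die at HR-fold
rates), the risk-factor distribution among survivors drifts downward with
age; the effective rates ignore that selection.  Under the default
parameterisation — where δ = 0.1 spans an e³ ≈ 20-fold incidence range
across the BMI support — the resulting bias is visible: the analytical
age-80 prevalence (64.0%) exceeds the simulated one (≈60.5%) by more than
the Monte-Carlo error of a 10000-person cohort, and the analytical curve
leaves the simulation's 95% band over much of ages 40–90.  With weaker
covariate effects the two routes coincide (tested: for a near-degenerate
risk factor the simulation matches the ODE within 3 Monte-Carlo standard
errors).  This bias is a property of the method under strong covariate
effects, not an implementation artefact — the competing-risk and
closed-form oracles in the test suite pin both routes independently.

## Discrete-event simulation

Failure times are drawn by inverting the cumulative hazard: solve
H(a₀, t) = −log U for t, with H computed by trapezoidal integration on a
0.01-year grid and the root refined inside the bracketing cell by the
stable closed-form root of the locally-quadratic H (exact for cell-wise
constant or linear hazards; tested against the Gompertz closed form by a
Kolmogorov–Smirnov test at the 1% level).  Competing first events use two
independent latent times (onset from λ, disease-free death from μ0) and
take the minimum — equivalent, for independent cause-specific hazards, to
sampling the total-hazard time and attributing the cause; the equivalence
is property-tested against the analytic exponential split.  If onset wins,
a post-onset death time is drawn from μ1 restricted beyond the onset age.
Individuals alive at the 110-year cap are censored there and still count as
alive (and as cases) up to the cap.

Randomness: a root `SeedSequence` spawns one substream per individual; the
substream's first uniform maps to the BMI through the inverse CDF, the next
two (plus a third on onset) drive the failure times.  Cohorts of different
sizes therefore share their leading individuals, and paired scenario runs
with one seed are coupled individual-by-individual (common random numbers),
which is what makes the ≈0.3-pp intervention effect estimable at n = 10000.
The cohort path exploits the separability of the default hazards (the
Z-factor is constant in age, so each individual's trapezoidal cumulative
hazard is an exact rescaling of two shared age integrals); it is tested to
agree with the generic per-individual inversion to 1e−5 years.

Prevalence at age a is cases/alive with a 95% Wilson score interval (Wilson
rather than Wald because it behaves at boundary prevalences); ages where
nobody is alive are flagged undefined, never fabricated.

## Aggregate ("overall") prevalence

Two definitions are provided.  The primary, simulation-side definition is
person-time weighting on integer ages 0–110: total case-person-years over
total alive-person-years.  The analytical counterpart
(`survival_weighted_prevalence`) is ∫ π S da / ∫ S da with S the survival
function from birth under the mean mortality (1 − π)μ0\* + π μ1\*.  Under
the defaults they agree to ≈0.25 pp (13.37% vs 13.62% at seed 1980), the
difference again tracing to survivor selection.

## Known limitations

* The risk factor is fixed for life; time-varying trajectories and
  interaction terms are out of scope.
* The ERM's fixed birth-cohort density makes it biased when covariate
  effects on mortality/incidence are strong (see above); it is exact for a
  degenerate covariate and accurate for weak effects.
* The simulation emulates exactly the model's assumptions (closed cohort,
  independent latent risks, constant HR).  Passing tests therefore
  demonstrate internal consistency of the two routes, not fidelity of the
  parametric hazards to any real population.
* Computational scaling is logged, never asserted: the analytical route's
  cost is independent of cohort size while the simulation grows linearly
  in n.
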