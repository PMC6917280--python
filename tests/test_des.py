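"""Tests for failure-time sampling, the cohort simulation and its estimators."""

import numpy as np
import pytest
from scipy import stats

from idmrisk import (
    CohortResult,
    LifeCourse,
    RateParameters,
    ScaledBetaDistribution,
    effective_rates_from_model,
    estimate_prevalence,
    overall_prevalence,
    sample_failure_time,
    simulate_cohort,
    simulate_individual,
    solve_prevalence_ode,
)


class TestSampleFailureTime:
    def test_constant_hazard_exact_inversion(self):
        # trapezoid integration is exact for constants: t = -log(u)/h
        t = sample_failure_time(lambda a: np.full_like(a, 0.1), 0.0, 200.0, np.exp(-1.0))
        assert t == pytest.approx(10.0, abs=1e-9)
        u = np.array([0.9, 0.5, 0.1])
        np.testing.assert_allclose(
            sample_failure_time(lambda a: np.full_like(a, 0.05), 0.0, 400.0, u),
            -np.log(u) / 0.05, atol=1e-9,
        )

    def test_zero_hazard_always_censored(self):
        t = sample_failure_time(lambda a: np.zeros_like(a), 0.0, 110.0, 0.5)
        assert np.isnan(t)

    def test_invalid_u_rejected(self):
        for u in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError, match="u must"):
                sample_failure_time(lambda a: np.ones_like(a), 0.0, 10.0, u)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="hazard"):
            sample_failure_time(lambda a: -np.ones_like(a), 0.0, 10.0, 0.5)

    def test_gompertz_draws_match_analytic_cdf(self, rng):
        """Empirical CDF of cumulative-hazard-inversion draws vs the closed
        Gompertz form Λ(t) = e^ϑ (e^{νt} − 1)/ν, KS at the 1% level."""
        theta, nu = -10.948, 0.095
        u = rng.random(100_000)
        t = sample_failure_time(lambda a: np.exp(theta + nu * a), 0.0, 200.0, u)
        assert not np.any(np.isnan(t))
        cdf = lambda x: 1.0 - np.exp(-np.exp(theta) * (np.exp(nu * x) - 1.0) / nu)
        stat = stats.kstest(t, cdf).statistic
        assert stat < 1.63 / np.sqrt(t.size)


LAM0, M0 = 0.05, 0.1


@pytest.fixture(scope="module")
def draws():
    rng = np.random.default_rng(424242)
    n = 100_000
    t1 = sample_failure_time(lambda a: np.full_like(a, LAM0), 0.0, 2000.0, rng.random(n))
    t2 = sample_failure_time(lambda a: np.full_like(a, M0), 0.0, 2000.0, rng.random(n))
    return t1, t2


class TestCompetingRisks:
    """With constant cause-specific hazards the latent-minimum construction
    must reproduce the analytic first-event law: time ~ Exp(λ0+m0), cause
    split λ0/(λ0+m0)."""

    LAM0, M0 = LAM0, M0

    def test_first_event_time_distribution(self, draws):
        t1, t2 = draws
        first = np.minimum(t1, t2)
        stat = stats.kstest(first, stats.expon(scale=1 / (self.LAM0 + self.M0)).cdf).statistic
        assert stat < 1.63 / np.sqrt(first.size)

    def test_cause_split(self, draws):
        t1, t2 = draws
        p_hat = np.mean(t1 < t2)
        p = self.LAM0 / (self.LAM0 + self.M0)
        se = np.sqrt(p * (1 - p) / t1.size)
        assert abs(p_hat - p) < 2.576 * se  # 1% two-sided

    def test_dominated_risk_never_reaches_onset(self, params, base_dist):
        # disease-free mortality overwhelming -> nobody gets ill
        huge = params.replace(theta=5.0)  # e^5 per year baseline mortality
        cohort = simulate_cohort(huge, base_dist, 500, seed=5)
        assert np.all(np.isnan(cohort.onset_age))


class TestSimulateIndividual:
    def test_same_stream_state_reproduces_record(self, params):
        lc1 = simulate_individual(params, 28.0, 110.0, np.random.default_rng(99))
        lc2 = simulate_individual(params, 28.0, 110.0, np.random.default_rng(99))
        assert lc1 == lc2

    def test_life_shapes_are_consistent(self, params, base_dist, rng):
        for z in base_dist.sample(50, rng):
            lc = simulate_individual(params, float(z), 110.0, rng)
            assert 0 < lc.death_age <= 110.0
            if lc.onset_age is not None:
                assert lc.onset_age < lc.death_age
            if lc.censored:
                assert lc.death_age == 110.0

    def test_onset_must_precede_death(self):
        with pytest.raises(ValueError, match="onset"):
            LifeCourse(0, 25.0, onset_age=70.0, death_age=60.0, censored=False)


class TestSimulateCohort:
    def test_identical_seed_identical_cohort(self, params, base_dist):
        c1 = simulate_cohort(params, base_dist, 200, seed=17)
        c2 = simulate_cohort(params, base_dist, 200, seed=17)
        assert c1.life_courses == c2.life_courses

    def test_single_individual_reproducible(self, params, base_dist):
        c = simulate_cohort(params, base_dist, 1, seed=3)
        assert c.n == 1 and len(c.life_courses) == 1
        assert c.life_courses[0] == simulate_cohort(params, base_dist, 1, seed=3).life_courses[0]

    def test_cohort_prefix_shared_across_sizes(self, params, base_dist):
        small = simulate_cohort(params, base_dist, 50, seed=23)
        big = simulate_cohort(params, base_dist, 120, seed=23)
        assert small.life_courses == big.life_courses[:50]

    def test_invalid_size_rejected(self, params, base_dist):
        with pytest.raises(ValueError):
            simulate_cohort(params, base_dist, 0, seed=1)

    def test_engine_matches_generic_individual_path(self, params, base_dist):
        """The cohort fast path (shared separable age integrals) must agree
        with per-individual generic cumulative-hazard inversion on the same
        substreams."""
        n, seed, cap = 60, 31, 110.0
        cohort = simulate_cohort(params, base_dist, n, seed=seed, age_cap=cap)
        children = np.random.SeedSequence(seed).spawn(n)
        for j, child in enumerate(children):
            rng = np.random.default_rng(child)
            z = float(base_dist.ppf(rng.random()))
            ref = simulate_individual(params, z, cap, rng)
            got = cohort.life_courses[j]
            assert got.z == pytest.approx(z, abs=1e-12)
            assert got.censored == ref.censored
            assert (got.onset_age is None) == (ref.onset_age is None)
            if ref.onset_age is not None:
                assert got.onset_age == pytest.approx(ref.onset_age, abs=1e-5)
            assert got.death_age == pytest.approx(ref.death_age, abs=1e-5)

    def test_common_random_numbers_couple_scenarios(self, params, base_dist, intervention_dist):
        base = simulate_cohort(params, base_dist, 300, seed=8)
        shifted = simulate_cohort(params, intervention_dist, 300, seed=8)
        # inverse-CDF coupling: intervention BMI pointwise <= base BMI
        assert np.all(shifted.z <= base.z)

    def test_degenerate_covariate_matches_ode(self, params):
        """When the risk factor is (nearly) constant at z, the mean-rate ODE
        with rates evaluated at z is exact, so the simulated prevalence must
        match it to Monte-Carlo error."""
        from idmrisk import EffectiveRates, incidence_rate, mortality_free, mortality_ill

        peaked = ScaledBetaDistribution(phi=1e6, psi=1e6, lower=17, upper=47)
        n = 40_000
        cohort = simulate_cohort(params, peaked, n, seed=12)
        curve = estimate_prevalence(cohort, np.arange(40.0, 91.0))
        z_mid = 32.0  # phi = psi concentrates at the support midpoint
        rates = EffectiveRates(
            lambda_star=lambda a: incidence_rate(params, a, z_mid),
            mu0_star=lambda a: mortality_free(params, a, z_mid),
            mu1_star=lambda a: mortality_ill(params, a, z_mid),
        )
        # start at birth: the simulation counts onsets before age 30 too
        ode = solve_prevalence_ode(rates, 0, 110, 0.0)
        for age, p_hat, lo, hi in zip(
            curve.ages, curve.prevalence, curve.ci_lower, curve.ci_upper
        ):
            p = ode.at(age)
            n_alive = np.sum(
                (cohort.death_age > age) | (cohort.censored & (cohort.death_age >= age))
            )
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_alive)
            assert abs(p_hat - p) < 3 * se + 1e-3


class TestEstimators:
    @pytest.fixture()
    def toy_cohort(self):
        # 20 alive at age 60; 5 of them cases
        records = []
        for j in range(5):
            records.append(LifeCourse(j, 25.0, onset_age=50.0, death_age=80.0, censored=False))
        for j in range(5, 20):
            records.append(LifeCourse(j, 25.0, onset_age=None, death_age=80.0, censored=False))
        for j in range(20, 25):
            records.append(LifeCourse(j, 25.0, onset_age=None, death_age=40.0, censored=False))
        return CohortResult(records, seed=0, scenario="toy", n=25, age_cap=110.0)

    def test_ratio_estimator(self, toy_cohort):
        curve = estimate_prevalence(toy_cohort, np.array([60.0]))
        assert curve.prevalence[0] == pytest.approx(5 / 20)

    def test_prevalence_zero_at_birth(self, toy_cohort):
        curve = estimate_prevalence(toy_cohort, np.array([0.0]))
        assert curve.prevalence[0] == 0.0

    def test_wilson_lower_bound_at_zero_cases(self):
        records = [
            LifeCourse(j, 25.0, onset_age=None, death_age=80.0, censored=False)
            for j in range(10)
        ]
        cohort = CohortResult(records, seed=0, scenario="", n=10, age_cap=110.0)
        curve = estimate_prevalence(cohort, np.array([50.0]))
        assert curve.prevalence[0] == 0.0
        assert curve.ci_lower[0] == 0.0

    def test_undefined_when_nobody_alive(self, toy_cohort):
        curve = estimate_prevalence(toy_cohort, np.array([50.0, 100.0]))
        assert not curve.defined[1] and np.isnan(curve.prevalence[1])
        assert curve.defined[0]

    def test_counts_monotone_structure(self, params, base_dist):
        cohort = simulate_cohort(params, base_dist, 2000, seed=2)
        ages = np.arange(0.0, 111.0)
        from idmrisk.des import _counts

        cases, alive = _counts(cohort, ages)
        assert np.all(cases <= alive) and np.all(alive <= cohort.n)

    def test_empty_grid_errors(self, params, base_dist):
        cohort = simulate_cohort(params, base_dist, 10, seed=2)
        with pytest.raises(ValueError):
            estimate_prevalence(cohort, np.array([150.0]))

    def test_overall_prevalence_single_individual(self):
        records = [LifeCourse(0, 25.0, onset_age=50.0, death_age=60.0, censored=False)]
        cohort = CohortResult(records, seed=0, scenario="", n=1, age_cap=100.0)
        # alive on integer ages 0..59 (60 ages), case on 50..59 (10 ages)
        assert overall_prevalence(cohort) == pytest.approx(10 / 60)

    def test_overall_prevalence_zero_without_disease(self):
        records = [
            LifeCourse(j, 25.0, onset_age=None, death_age=70.0, censored=False)
            for j in range(4)
        ]
        cohort = CohortResult(records, seed=0, scenario="", n=4, age_cap=110.0)
        assert overall_prevalence(cohort) == 0.0

    def test_output_determinism_bytes(self, params, base_dist, tmp_path):
        import filecmp

        for name in ("a.csv", "b.csv"):
            cohort = simulate_cohort(params, base_dist, 500, seed=77)
            estimate_prevalence(cohort).to_csv(tmp_path / name)
        assert filecmp.cmp(tmp_path / "a.csv", tmp_path / "b.csv", shallow=False)
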