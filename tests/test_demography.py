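import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harvestlab.demography import (
    CohortTrack,
    LifeTable,
    MortalityEstimate,
    elasticity,
    generation_time,
    generations_per_year,
    observed_mortality,
    population_harvest_fraction,
    single_interval_mortality,
    total_mortality_mark_recapture,
)
from harvestlab.ibm import (
    FecundityParams,
    GrowthParams,
    MaturationParams,
    SimConfig,
    initialize_population,
    simulate_cohort_decay,
    step_week,
)


def geometric_track(mu, p_hs, dt, n_cycles, n0=1000.0):
    """Noiseless decay N_{t+1} = e^(-mu dt) * p_hs * N_t with float counts."""
    track = CohortTrack(cohort="exact")
    track.append(0, 0.0, n0, 1.0)
    n = n0
    for c in range(1, n_cycles + 1):
        n = math.exp(-mu * dt) * p_hs * n
        track.append(c, dt, n, p_hs)
    return track


class TestObservedMortality:
    def test_zero_deaths(self):
        assert observed_mortality(0, 500) == 0.0

    def test_arithmetic(self):
        assert observed_mortality(25, 500) == pytest.approx(0.05)

    def test_errors(self):
        with pytest.raises(ValueError):
            observed_mortality(1, 0)
        with pytest.raises(ValueError):
            observed_mortality(11, 10)

    def test_simulator_oracle(self):
        # no harvest, mu=0.01/wk: 6-week observed rate ~ 1 - e^(-0.06)
        mu = 0.01
        reps, n0 = 20, 500
        cfg = SimConfig(n_initial=n0, natural_mortality_week=mu,
                        growth=GrowthParams(c=0.0),
                        maturation=MaturationParams(lp50_mm=1e9, deterministic=True),
                        fecundity=FecundityParams(intercept=-100.0, length_slope=0.0))
        rng = np.random.default_rng(30)
        rates = []
        for k in range(reps):
            state = initialize_population(cfg, np.random.default_rng(31 + k))
            for _ in range(6):
                step_week(state, cfg, rng)
            rates.append(observed_mortality(n0 - state.abundance, n0))
        p = 1 - math.exp(-6 * mu)
        se = math.sqrt(p * (1 - p) / n0 / reps)
        assert abs(np.mean(rates) - p) < 3 * se


class TestMarkRecapture:
    def test_no_decay_gives_zero(self):
        track = geometric_track(mu=0.0, p_hs=1.0, dt=6.0, n_cycles=3, n0=100)
        est = total_mortality_mark_recapture(track, n_boot=100)
        assert est.mu_week == pytest.approx(0.0, abs=1e-12)

    def test_single_interval_closed_form(self):
        mu = single_interval_mortality(200, 131, 0.8, 6.0)
        assert mu == pytest.approx(math.log(160 / 131) / 6.0)
        assert mu == pytest.approx(0.0333, abs=5e-4)

    @pytest.mark.parametrize("mu", np.round(np.arange(0.0, 0.11, 0.01), 3).tolist())
    @pytest.mark.parametrize("p_hs", [0.5, 0.8, 1.0])
    def test_exact_on_noiseless_grid(self, mu, p_hs):
        track = geometric_track(mu, p_hs, dt=6.0, n_cycles=6)
        est = total_mortality_mark_recapture(track, n_boot=50)
        assert abs(est.mu_week - mu) <= 1e-10

    def test_mean_method_exact_too(self):
        track = geometric_track(0.05, 0.8, dt=6.0, n_cycles=5)
        est = total_mortality_mark_recapture(track, method="mean", n_boot=50)
        assert abs(est.mu_week - 0.05) <= 1e-10

    def test_negative_estimate_floored_with_warning(self):
        track = CohortTrack(cohort="grow")
        track.append(0, 0.0, 100.0, 1.0)
        track.append(1, 6.0, 120.0, 1.0)
        with pytest.warns(UserWarning, match="floored"):
            est = total_mortality_mark_recapture(track, n_boot=50)
        assert est.mu_week == 0.0

    def test_zero_count_truncates(self):
        track = CohortTrack(cohort="trunc")
        for c, (dt, n) in enumerate([(0.0, 100.0), (6.0, 50.0), (6.0, 0.0), (6.0, 0.0)]):
            track.append(c, dt, n, 1.0)
        est = total_mortality_mark_recapture(track, n_boot=50)
        assert est.mu_week == pytest.approx(math.log(2) / 6.0)

    def test_stochastic_recovery(self):
        # generator-level truth: cohort of 1000, recovered within 3 bootstrap SE
        mu_true = 0.0424
        rng = np.random.default_rng(40)
        tracks = [simulate_cohort_decay(1000, mu_true, 0.8, 6.0, 8, rng) for _ in range(5)]
        est = total_mortality_mark_recapture(tracks, seed=41)
        assert abs(est.mu_week - mu_true) < 3 * est.se

    def test_convergence_with_cohort_size(self):
        mu_true = 0.05
        errs = []
        for n0 in (100, 1000, 10000):
            ests = []
            for k in range(20):
                rng = np.random.default_rng(7000 + 17 * n0 + k)
                tr = simulate_cohort_decay(n0, mu_true, 0.9, 6.0, 6, rng)
                ests.append(total_mortality_mark_recapture(tr, n_boot=10).mu_week)
            errs.append(abs(np.mean(ests) - mu_true))
        assert errs[2] < errs[0]
        assert errs[2] < 5e-4

    def test_estimate_invariants(self):
        with pytest.raises(ValueError):
            MortalityEstimate(mu_week=-0.1, ci=(-0.2, 0.0), method="observed", n_intervals=1)
        with pytest.raises(ValueError):
            MortalityEstimate(mu_week=0.1, ci=(0.2, 0.3), method="observed", n_intervals=1)


class TestGenerationTime:
    def test_single_age_class(self):
        table = LifeTable(x=[0, 5], lx=[1.0, 0.3], mx=[0.0, 2.0])
        assert generation_time(table, cycle_weeks=6) == pytest.approx(5 * 42.0)

    def test_hand_oracle(self):
        table = LifeTable(x=[0, 1, 2], lx=[1.0, 0.5, 0.25], mx=[0.0, 2.0, 2.0])
        # T = (0 + 1*0.5*2 + 2*0.25*2) / (0.5*2 + 0.25*2) = 2/1.5 cycles
        assert generation_time(table, cycle_weeks=6) == pytest.approx(2.0 / 1.5 * 42.0)

    def test_zero_reproduction_raises(self):
        table = LifeTable(x=[0, 1], lx=[1.0, 0.5], mx=[0.0, 0.0])
        with pytest.raises(ValueError, match="net reproduction"):
            generation_time(table, cycle_weeks=6)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_fecundity_rescaling(self, scale):
        mx = np.array([0.0, 1.0, 3.0, 2.0])
        t1 = generation_time(LifeTable([0, 1, 2, 3], [1, 0.6, 0.3, 0.1], mx), 6)
        t2 = generation_time(LifeTable([0, 1, 2, 3], [1, 0.6, 0.3, 0.1], mx * scale), 6)
        assert t1 == pytest.approx(t2)

    def test_life_table_validation(self):
        with pytest.raises(ValueError):
            LifeTable(x=[0, 1], lx=[0.9, 0.5], mx=[0, 1])     # l0 != 1
        with pytest.raises(ValueError):
            LifeTable(x=[0, 1], lx=[1.0, 1.2], mx=[0, 1])     # increasing lx
        with pytest.raises(ValueError):
            LifeTable(x=[0, 1], lx=[1.0, 0.5], mx=[0, -1])    # negative mx

    def test_generations_per_year(self):
        assert round(generations_per_year(267.0), 1) == 1.4


class TestElasticity:
    def test_trait_unchanged(self):
        res = elasticity(10.0, 10.0, 100.0, 80.0)
        assert res.elasticity == 0.0

    def test_half(self):
        res = elasticity(10.0, 9.0, 100.0, 80.0)
        assert res.elasticity == pytest.approx(0.5)

    def test_opposite_sign(self):
        res = elasticity(10.0, 10.5, 100.0, 90.0)
        assert res.elasticity == pytest.approx(-0.5)

    def test_zero_biomass_change_flagged_undefined(self):
        res = elasticity(10.0, 9.0, 100.0, 100.0)
        assert not res.defined
        assert res.elasticity is None

    @given(t0=st.floats(1.0, 100.0), dt=st.floats(-0.5, 0.5),
           b0=st.floats(1.0, 100.0), db=st.floats(0.05, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_unit_invariance(self, t0, dt, b0, db):
        t1 = t0 * (1 + dt)
        b1 = b0 * (1 + db)
        e = elasticity(t0, t1, b0, b1).elasticity
        # flip the trait change -> elasticity negates
        e_flip = elasticity(t0, t0 * (1 - dt), b0, b1).elasticity
        assert e_flip == pytest.approx(-e, rel=1e-9, abs=1e-12)
        # rescale units of trait and biomass -> unchanged
        e_scaled = elasticity(t0 * 25.4, t1 * 25.4, b0 * 1000, b1 * 1000).elasticity
        assert e_scaled == pytest.approx(e, rel=1e-9, abs=1e-12)


class TestHarvestFraction:
    def test_p60_equal_counts(self):
        assert population_harvest_fraction(0.60, "positive", 500, 500) == pytest.approx(0.30)

    def test_p25_equal_counts(self):
        assert population_harvest_fraction(0.25, "positive", 500, 500) == pytest.approx(0.125)
        assert population_harvest_fraction(0.25, "negative", 500, 500) == pytest.approx(0.125)

    def test_no_eligible_fish(self):
        assert population_harvest_fraction(0.5, "positive", 0, 300) == 0.0

    def test_random_is_p_half_always(self):
        assert population_harvest_fraction(0.4, "random", 10, 990) == pytest.approx(0.2)

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            population_harvest_fraction(0.5, "positive", 0, 0)
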