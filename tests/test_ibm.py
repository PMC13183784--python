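import math

import numpy as np
import pytest

from harvestlab._util import ConfigError, round_half_up
from harvestlab.ibm import (
    EventLog,
    FecundityParams,
    GrowthParams,
    MaturationParams,
    SimConfig,
    apply_harvest,
    census,
    initialize_population,
    mark_and_track_cohort,
    simulate_cohort_decay,
    step_week,
)

from conftest import make_state


class TestInitialize:
    def test_even_sex_split_140(self):
        state = initialize_population(SimConfig(n_initial=140, seed=1))
        assert state.abundance == 140
        assert (state.sex == 0).sum() == 70
        assert (state.sex == 1).sum() == 70

    def test_empty_population(self):
        state = initialize_population(SimConfig(n_initial=0))
        assert state.abundance == 0
        assert state.biomass_g == 0.0

    def test_odd_count_parity(self):
        state = initialize_population(SimConfig(n_initial=101, seed=2))
        males = int((state.sex == 0).sum())
        females = int((state.sex == 1).sum())
        assert abs(males - females) == 1

    def test_deterministic_given_seed(self):
        a = initialize_population(SimConfig(n_initial=50, seed=42))
        b = initialize_population(SimConfig(n_initial=50, seed=42))
        np.testing.assert_array_equal(a.length, b.length)
        np.testing.assert_array_equal(a.sex, b.sex)
        np.testing.assert_array_equal(a.age, b.age)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="harvest_proportion"):
            initialize_population(SimConfig(harvest_proportion=1.5))
        with pytest.raises(ConfigError, match="census_fraction"):
            initialize_population(SimConfig(census_fraction=0.0))
        with pytest.raises(ConfigError, match="cycle_weeks"):
            initialize_population(SimConfig(cycle_weeks=0))

    def test_weight_consistent_with_allometry(self):
        cfg = SimConfig(n_initial=30, seed=3)
        state = initialize_population(cfg)
        np.testing.assert_allclose(state.weight, cfg.growth.weight_from_length(state.length))

    def test_biomass_equals_sum_of_weights(self):
        state = initialize_population(SimConfig(n_initial=80, seed=4))
        assert state.biomass_g == pytest.approx(state.weight.sum())


class TestStepWeek:
    def test_no_event_week_keeps_abundance(self, quiet_config):
        quiet_config.n_initial = 60
        state = initialize_population(quiet_config, np.random.default_rng(0))
        n0 = state.abundance
        step_week(state, quiet_config, np.random.default_rng(1))
        assert state.abundance == n0
        assert state.week == 1

    def test_huge_mortality_kills_nearly_all(self, quiet_config):
        quiet_config.n_initial = 200
        quiet_config.natural_mortality_week = 10.0
        state = initialize_population(quiet_config, np.random.default_rng(5))
        step_week(state, quiet_config, np.random.default_rng(6))
        # E[survivors] = 200 * e^-10 ~ 0.009
        assert state.abundance <= 3

    def test_binomial_survival_oracle(self, quiet_config):
        # mean survivors over replicates within 3 SE of N * e^(-mu)
        mu = 0.0718
        n = 1000
        reps = 2000
        quiet_config.n_initial = n
        quiet_config.natural_mortality_week = mu
        p = math.exp(-mu)
        base = initialize_population(quiet_config, np.random.default_rng(7))
        rng = np.random.default_rng(8)
        survivors = np.empty(reps)
        for k in range(reps):
            state = make_state(base.length.copy(), config=quiet_config)
            step_week(state, quiet_config, rng)
            survivors[k] = state.abundance
        expected = n * p
        se = math.sqrt(n * p * (1 - p) / reps)
        assert abs(survivors.mean() - expected) < 3 * se

    def test_mature_is_monotone(self):
        cfg = SimConfig(n_initial=150, seed=9,
                        maturation=MaturationParams(lp50_mm=14.0, slope=1.0))
        state = initialize_population(cfg, np.random.default_rng(9))
        rng = np.random.default_rng(10)
        prev_mature = {int(i): bool(m) for i, m in zip(state.ids, state.mature)}
        for _ in range(30):
            step_week(state, cfg, rng)
            for i, m in zip(state.ids, state.mature):
                if prev_mature.get(int(i), False):
                    assert bool(m), "maturity must never revert"
                prev_mature[int(i)] = bool(m)

    def test_deaths_logged_once(self, quiet_config):
        quiet_config.n_initial = 300
        quiet_config.natural_mortality_week = 0.3
        state = initialize_population(quiet_config, np.random.default_rng(11))
        log = EventLog()
        rng = np.random.default_rng(12)
        for _ in range(10):
            step_week(state, quiet_config, rng, log)
        dead_ids = [d[1] for d in log.deaths]
        assert len(dead_ids) == len(set(dead_ids))
        assert state.abundance + len(dead_ids) == 300


class TestApplyHarvest:
    def _mixed_state(self):
        lengths = [18.0] * 10 + [12.0] * 10
        return make_state(lengths)

    def test_positive_half_above(self, rng):
        state = self._mixed_state()
        removed = apply_harvest(state, SimConfig(regime="positive", harvest_proportion=0.5), rng)
        assert len(removed) == 5
        assert all(ind.length_mm > 16.0 for ind in removed)
        assert state.abundance == 15

    def test_zero_p_is_identity(self, rng):
        state = self._mixed_state()
        removed = apply_harvest(state, SimConfig(regime="positive", harvest_proportion=0.0), rng)
        assert removed == []
        assert state.abundance == 20

    def test_negative_p1_exhaustive(self, rng):
        state = self._mixed_state()
        removed = apply_harvest(state, SimConfig(regime="negative", harvest_proportion=1.0), rng)
        assert len(removed) == 10
        assert all(ind.length_mm <= 16.0 for ind in removed)
        assert np.all(state.length > 16.0)

    def test_threshold_exactly_16_goes_to_negative(self, rng):
        state = make_state([16.0] * 10)
        removed = apply_harvest(state, SimConfig(regime="positive", harvest_proportion=1.0), rng)
        assert removed == []
        removed = apply_harvest(state, SimConfig(regime="negative", harvest_proportion=1.0), rng)
        assert len(removed) == 10

    def test_random_regime_takes_p_half(self, rng):
        state = self._mixed_state()
        removed = apply_harvest(state, SimConfig(regime="random", harvest_proportion=0.6), rng)
        assert len(removed) == round_half_up(0.3 * 20)

    def test_invalid_p_raises(self, rng):
        state = self._mixed_state()
        with pytest.raises(ConfigError):
            apply_harvest(state, SimConfig(), rng, p_override=1.2)

    def test_population_level_fraction_converges_to_p_half(self):
        # equal numbers above/below: both selective regimes remove ~P/2 overall
        P = 0.5
        reps = 400
        rng = np.random.default_rng(13)
        for regime in ("positive", "negative"):
            fracs = []
            for _ in range(reps):
                state = make_state([18.0] * 50 + [12.0] * 50)
                removed = apply_harvest(state, SimConfig(regime=regime, harvest_proportion=P), rng)
                fracs.append(len(removed) / 100)
            assert np.mean(fracs) == pytest.approx(P / 2, abs=1e-9)


class TestCensus:
    def test_quarter_of_400(self, rng):
        state = make_state(np.linspace(10, 25, 400))
        recs = census(state, SimConfig(census_fraction=0.25), rng)
        assert len(recs) == 100
        assert state.abundance == 400  # non-destructive

    def test_empty_population(self, rng):
        state = make_state([])
        assert census(state, SimConfig(), rng) == []

    def test_rounding_3_fish(self, rng):
        state = make_state([10.0, 11.0, 12.0])
        recs = census(state, SimConfig(census_fraction=0.25), rng)
        assert len(recs) == round_half_up(0.75) == 1

    def test_invalid_fraction(self, rng):
        state = make_state([10.0])
        cfg = SimConfig()
        cfg.census_fraction = 1.5
        with pytest.raises(ConfigError, match="census_fraction"):
            census(state, cfg, rng)

    def test_records_reference_live_fish(self, rng):
        state = make_state(np.linspace(10, 25, 40))
        recs = census(state, SimConfig(), rng)
        live = set(int(i) for i in state.ids)
        assert all(r.id in live for r in recs)
        assert len({r.id for r in recs}) == len(recs)  # without replacement


class TestCohorts:
    def test_mark_empty_selection_raises(self, rng):
        state = make_state([10.0, 12.0])
        with pytest.raises(ValueError, match="matched no live fish"):
            mark_and_track_cohort(state, "c0", np.zeros(2, dtype=bool))

    def test_counts_constant_without_events(self, quiet_config):
        quiet_config.n_initial = 50
        state = initialize_population(quiet_config, np.random.default_rng(14))
        track = mark_and_track_cohort(state, "c0", np.ones(50, dtype=bool))
        rng = np.random.default_rng(15)
        for cyc in range(1, 4):
            for _ in range(6):
                step_week(state, quiet_config, rng)
            n = sum(1 for c in state.cohort if c == "c0")
            track.append(cycle=cyc, dt_weeks=6.0, count=float(n), p_hs=1.0)
        assert track.counts == [50.0, 50.0, 50.0, 50.0]

    def test_deterministic_halving(self):
        # P_hs = 0.5 exact harvest, no natural mortality
        from harvestlab.demography import CohortTrack
        track = CohortTrack(cohort="halve")
        n = 100.0
        track.append(0, 0.0, n, 1.0)
        for cyc in range(1, 4):
            n *= 0.5
            track.append(cyc, 6.0, n, 0.5)
        assert track.counts == [100.0, 50.0, 25.0, 12.5]

    def test_expected_decay_oracle(self):
        # E[N1] = 200 * e^(-0.2) * 0.8 ~ 131.0; mean over 2000 reps within 3 SE
        reps = 2000
        rng = np.random.default_rng(16)
        n1 = np.empty(reps)
        for k in range(reps):
            tr = simulate_cohort_decay(200, mu_week=0.2 / 6, p_hs=0.8,
                                       dt_weeks=6.0, n_cycles=1, rng=rng)
            n1[k] = tr.counts[1]
        p_tot = math.exp(-0.2) * 0.8
        expected = 200 * p_tot
        se = math.sqrt(200 * p_tot * (1 - p_tot) / reps)
        assert abs(n1.mean() - expected) < 3 * se
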