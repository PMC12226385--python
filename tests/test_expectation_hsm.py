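"""Forecasting rules, fitness bookkeeping, and heuristic selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprnet.expectation_hsm import (
    N_HEURISTICS,
    HeuristicState,
    HsmParams,
    SnapshotHistory,
    forecast,
    sample_heuristic,
    selection_probabilities,
    update_fitness,
)

unit = st.floats(min_value=0, max_value=1, allow_nan=False)


def history(z_prev, z_prev2, z_ave=None, count=3):
    z_ave = z_prev if z_ave is None else z_ave
    return SnapshotHistory(z_prev=z_prev, z_prev2=z_prev2, z_sum=z_ave * count, count=count)


class TestForecast:
    @pytest.mark.parametrize("h", [1, 2, 3, 4])
    def test_constant_history_is_fixed_point(self, h):
        c = 0.37
        assert forecast(h, history(c, c, c), c, HsmParams()) == pytest.approx(c)

    def test_trend_and_contrarian_values(self):
        hist = history(0.5, 0.4)
        p = HsmParams()
        assert forecast(2, hist, 0.0, p) == pytest.approx(0.5 + 0.44 * 0.1)
        assert forecast(3, hist, 0.0, p) == pytest.approx(0.5 - 0.44 * 0.1)

    def test_anchoring_value(self):
        hist = history(0.5, 0.4, z_ave=0.6)
        assert forecast(4, hist, 0.0, HsmParams()) == pytest.approx(0.65)

    def test_adaptive_blends_previous_forecast(self):
        hist = history(0.8, 0.1)
        got = forecast(1, hist, 0.2, HsmParams(beta1=0.63))
        assert got == pytest.approx(0.63 * 0.8 + 0.37 * 0.2)

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            forecast(5, history(0.5, 0.5), 0.5, HsmParams())

    @settings(max_examples=200, deadline=None)
    @given(z1=unit, z2=unit, zave=unit, prev=unit,
           h=st.integers(min_value=1, max_value=4))
    def test_forecasts_clipped_to_unit_interval(self, z1, z2, zave, prev, h):
        hist = history(z1, z2, zave)
        assert 0.0 <= forecast(h, hist, prev, HsmParams()) <= 1.0


class TestFitness:
    def test_perfect_forecast_keeps_zero(self):
        state = HeuristicState.cold_start(0.5)
        update_fitness(state, SnapshotHistory.cold_start(0.5), 0.5, HsmParams())
        assert state.fitness == [0.0] * N_HEURISTICS

    def test_single_update_value(self):
        state = HeuristicState.cold_start(0.5)
        state.fitness = [-0.02] * N_HEURISTICS
        update_fitness(state, SnapshotHistory.cold_start(0.5), 0.6, HsmParams(eta=0.7))
        assert state.fitness[0] == pytest.approx(-0.01 + 0.7 * -0.02)

    def test_memoryless_limit(self):
        state = HeuristicState.cold_start(0.2)
        state.fitness = [-5.0] * N_HEURISTICS
        update_fitness(state, SnapshotHistory.cold_start(0.2), 0.3, HsmParams(eta=0.0))
        assert state.fitness[0] == pytest.approx(-0.01)

    def test_matches_discounted_sum_closed_form(self):
        # drive the recursion with a controlled error sequence and compare
        # against sum_k eta^k * (-e_{T-k}^2)
        eta = 0.7
        rng = np.random.default_rng(5)
        errors = rng.uniform(-0.3, 0.3, size=12)
        state = HeuristicState.cold_start(0.5)
        hist = SnapshotHistory.cold_start(0.5)
        for e in errors:
            z_obs = min(1.0, max(0.0, state.forecasts[0] + e))
            e_actual = z_obs - state.forecasts[0]
            update_fitness(state, hist, z_obs, HsmParams(eta=eta))
            errors_seen = getattr(state, "_seen", [])
            errors_seen.append(e_actual)
            state._seen = errors_seen
        expected = sum(
            eta**k * -(err**2) for k, err in enumerate(reversed(state._seen))
        )
        assert state.fitness[0] == pytest.approx(expected, abs=1e-12)

    def test_forecasts_refreshed_after_update(self):
        state = HeuristicState.cold_start(0.5)
        hist = SnapshotHistory.cold_start(0.5)
        update_fitness(state, hist, 0.9, HsmParams())
        # trend rule should extrapolate the 0.5 -> 0.9 jump (clipped)
        assert state.forecasts[1] == pytest.approx(min(1.0, 0.9 + 0.44 * 0.4))
        assert hist.z_prev == 0.9 and hist.z_prev2 == 0.5
        assert hist.z_ave == pytest.approx((0.5 + 0.9) / 2)

    def test_two_lag_adaptive_switch(self):
        params = HsmParams(adaptive_two_lag=True)
        state = HeuristicState.cold_start(0.5)
        hist = SnapshotHistory.cold_start(0.5)
        update_fitness(state, hist, 0.9, params)   # adaptive_prev2 becomes 0.5
        f1_after_first = state.forecasts[0]
        update_fitness(state, hist, 0.7, params)
        # blends newest snapshot with the forecast from TWO events back (0.5)
        assert state.forecasts[0] == pytest.approx(0.63 * 0.7 + 0.37 * 0.5)
        assert state.adaptive_prev2 == pytest.approx(f1_after_first)


class TestSelection:
    def test_incumbent_bonus_with_equal_fitness(self):
        state = HeuristicState.cold_start(0.5, current=2)
        probs = selection_probabilities(state, HsmParams(rho=0.9))
        assert probs[1] == pytest.approx(0.9 + 0.1 * 0.25)
        for k in (0, 2, 3):
            assert probs[k] == pytest.approx(0.025)

    def test_no_inertia_equal_fitness_uniform(self):
        state = HeuristicState.cold_start(0.5)
        probs = selection_probabilities(state, HsmParams(rho=0.0))
        assert np.allclose(probs, 0.25)

    def test_argmax_limit(self):
        state = HeuristicState.cold_start(0.5)
        state.fitness = [-0.5, -0.1, -0.5, -0.5]
        probs = selection_probabilities(state, HsmParams(rho=0.0, phi=1e4))
        assert probs[1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_intensity_ignores_fitness(self):
        state = HeuristicState.cold_start(0.5, current=3)
        state.fitness = [-9.0, -0.001, -4.0, -2.0]
        probs = selection_probabilities(state, HsmParams(rho=0.6, phi=0.0))
        assert probs[2] == pytest.approx(0.6 + 0.4 * 0.25)
        assert probs[0] == pytest.approx(0.1)

    @settings(max_examples=100, deadline=None)
    @given(fitness=st.lists(st.floats(min_value=-50, max_value=0), min_size=4, max_size=4),
           current=st.integers(min_value=1, max_value=4),
           rho=st.floats(min_value=0, max_value=1))
    def test_valid_distribution_and_inertia_floor(self, fitness, current, rho):
        state = HeuristicState.cold_start(0.5, current=current)
        state.fitness = fitness
        probs = selection_probabilities(state, HsmParams(rho=rho, phi=100.0))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= -1e-15).all()
        assert probs[current - 1] >= rho - 1e-12

    def test_softmax_overflow_safe(self):
        state = HeuristicState.cold_start(0.5)
        state.fitness = [0.0, -1000.0, -0.5, -2.0]
        probs = selection_probabilities(state, HsmParams(phi=100.0))
        assert np.isfinite(probs).all()


class TestSampling:
    def test_degenerate(self, rng):
        assert sample_heuristic(np.array([1.0, 0, 0, 0]), rng) == 1
        assert sample_heuristic(np.array([0, 0, 0, 1.0]), rng) == 4

    def test_uniform_frequencies(self):
        rng = np.random.default_rng(99)
        probs = np.full(4, 0.25)
        draws = np.array([sample_heuristic(probs, rng) for _ in range(100_000)])
        freqs = np.bincount(draws, minlength=5)[1:] / draws.size
        se = np.sqrt(0.25 * 0.75 / draws.size)
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_reproducible(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        a = [sample_heuristic(p, np.random.default_rng(1)) for _ in range(5)]
        b = [sample_heuristic(p, np.random.default_rng(1)) for _ in range(5)]
        assert a == b


def test_invalid_params():
    with pytest.raises(ValueError):
        HsmParams(beta3=0.1)
    with pytest.raises(ValueError):
        HsmParams(rho=1.5)
    with pytest.raises(ValueError):
        HsmParams(eta=-0.1)
    with pytest.raises(ValueError):
        HsmParams(phi=-1)
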