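import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtpolarity import (
    DynamicsParams,
    MicrotubuleArray,
    TubulinPool,
    advance_end_states,
    apply_polymerization,
    catastrophe_rate,
    sample_growth_run_lengths,
    simulate_lifetimes,
    estimate_exit_probability,
    switch_probability,
)

DT = 1.0 / 60.0


def make_array(intervals, params, is_meo=None, growing=True):
    arr = MicrotubuleArray(len(intervals))
    for i, (lo, up) in enumerate(intervals):
        arr.lower[i], arr.upper[i] = lo, up
    if is_meo is not None:
        arr.is_meo[:] = is_meo
    arr.up_grow[:] = growing
    arr.lo_grow[:] = growing
    arr.bind_params(params)
    return arr


class TestCatastropheRate:
    def test_at_characteristic_length_equals_printed_rate(self, params):
        assert catastrophe_rate(20.0, "plus", params) == pytest.approx(0.5)
        assert catastrophe_rate(20.0, "minus", params) == pytest.approx(0.25)

    def test_linear_below_characteristic_length(self, params):
        # 0.25 + 0.01 * (10 - 20)
        assert catastrophe_rate(10.0, "minus", params) == pytest.approx(0.15)

    def test_clamped_at_floor(self):
        p = DynamicsParams(lambda_tilde_plus=0.1, gamma=0.01, L0=20.0,
                           lambda_min=0.05)
        assert catastrophe_rate(10.0, "plus", p) == pytest.approx(0.05)

    def test_negative_length_rejected(self, params):
        with pytest.raises(ValueError):
            catastrophe_rate(-1.0, "plus", params)


class TestSwitchProbability:
    def test_closed_form(self):
        assert switch_probability(0.0, DT) == 0.0
        assert switch_probability(0.5, DT) == pytest.approx(
            1.0 - np.exp(-1.0 / 120.0)
        )
        assert switch_probability(1e9, DT) == pytest.approx(1.0)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(deadline=None)
    def test_monotone_in_rate_and_bounded(self, r1, r2):
        lo, hi = sorted((r1, r2))
        p_lo, p_hi = switch_probability(lo, DT), switch_probability(hi, DT)
        assert 0.0 <= p_lo <= p_hi <= 1.0


class TestAdvanceEndStates:
    def test_zero_rates_leave_states_unchanged(self, rng):
        p = DynamicsParams(lambda_tilde_plus=0, lambda_tilde_minus=0,
                           lambda_rescue_plus=0, lambda_rescue_minus=0,
                           gamma=0, lambda_min=0)
        arr = make_array([(0, 20)] * 10, p)
        advance_end_states(arr, p, DT, rng)
        assert arr.up_grow.all() and arr.lo_grow.all()

    def test_huge_rescue_rate_saturates(self, rng):
        p = DynamicsParams(lambda_rescue_plus=1e6, lambda_rescue_minus=1e6,
                           lambda_tilde_plus=0, lambda_tilde_minus=0,
                           gamma=0, lambda_min=0)
        arr = make_array([(0, 20)] * 50, p, growing=False)
        advance_end_states(arr, p, DT, rng)
        assert arr.up_grow.all() and arr.lo_grow.all()

    def test_flip_frequency_matches_switch_probability(self, params, rng):
        # 1e5 independent growing plus ends at L0 for one step
        n = 100_000
        arr = make_array([(0.0, params.L0)] * n, params)
        advance_end_states(arr, params, DT, rng)
        p = switch_probability(0.5, DT)
        freq = 1.0 - arr.up_grow.mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 3 * se


class TestApplyPolymerization:
    def test_displacement_speeds(self, params):
        # PEO [5,10], both ends growing: plus +6/60 up, minus -0.75/60 down
        arr = make_array([(5.0, 10.0)], params)
        pool = TubulinPool(free=np.inf, total=np.inf)
        apply_polymerization(arr, pool, 20.0, params, DT)
        assert arr.lower[0] == pytest.approx(5.0 - 0.75 / 60.0)
        assert arr.upper[0] == pytest.approx(10.0 + 0.1)

    def test_boundary_clipping(self, params):
        arr = make_array([(10.0, 19.95)], params)
        pool = TubulinPool(free=100.0, total=100.0 + 9.95)
        apply_polymerization(arr, pool, 20.0, params, DT)
        assert arr.upper[0] == 20.0
        # tubulin not consumed because of clipping stays free
        assert pool.free + (arr.upper[0] - arr.lower[0]) == pytest.approx(
            pool.total
        )

    def test_full_catastrophe_detected_and_credited(self, params):
        arr = make_array([(10.0, 10.05)], params, growing=False)
        pool = TubulinPool(free=1.0, total=1.05)
        dead = apply_polymerization(arr, pool, 20.0, params, DT)
        assert list(dead) == [0]
        assert not arr.alive[0]
        assert pool.free == pytest.approx(1.05)

    def test_tubulin_rationing_scales_growth_and_conserves(self, params):
        # two growing MTs demand (6+0.75)/60*2 = 0.225 um but only 0.1 free
        arr = make_array([(5.0, 10.0), (12.0, 15.0)], params)
        pool = TubulinPool(free=0.1, total=0.1 + 5.0 + 3.0)
        apply_polymerization(arr, pool, 70.0, params, DT)
        mass = (arr.upper - arr.lower).sum()
        assert pool.free + mass == pytest.approx(pool.total, rel=1e-12)
        assert pool.free >= 0.0
        # growth happened but was throttled below the unconstrained request
        assert 8.0 < mass < 8.0 + 0.225

    def test_shrinking_releases_to_pool(self, params):
        arr = make_array([(5.0, 15.0)], params, growing=False)
        pool = TubulinPool(free=0.0, total=10.0)
        apply_polymerization(arr, pool, 20.0, params, DT)
        released = (6.0 + 3.5) / 60.0
        assert pool.free == pytest.approx(released)
        assert arr.upper[0] - arr.lower[0] == pytest.approx(10.0 - released)


class TestLifetimes:
    def test_degenerate_no_rescue_short_excursions(self, rng):
        p = DynamicsParams(lambda_tilde_plus=200.0, lambda_tilde_minus=200.0,
                           lambda_rescue_plus=0.0, lambda_rescue_minus=0.0,
                           gamma=0.0, T_tot=np.inf)
        exc, life = simulate_lifetimes(200, p, DT, rng)
        # immediate catastrophe at both ends: nearly no growth ever
        assert np.mean(exc < 1.0) > 0.95
        assert (life > 0).all()

    def test_exit_probability_trivial_thresholds(self, unlimited_params, rng):
        p0, _ = estimate_exit_probability(50, 0.0, unlimited_params, DT, rng)
        assert p0 == 1.0
        p_inf, _ = estimate_exit_probability(50, 1e9, unlimited_params, DT, rng)
        assert p_inf == 0.0

    def test_excursion_nonnegative_and_lifetime_positive(self, unlimited_params, rng):
        exc, life = simulate_lifetimes(100, unlimited_params, DT, rng)
        assert (exc >= 0).all() and (life > 0).all()


class TestRunLengths:
    def test_mean_growth_run_length_matches_telegraph(self, params, rng):
        """gamma=0 regime: mean plus run 12 um, minus run 3 um (vg / lambda)."""
        p = DynamicsParams(gamma=0.0)
        runs_plus = sample_growth_run_lengths("plus", p, DT, rng,
                                              n_ends=400, n_steps=6000)
        runs_minus = sample_growth_run_lengths("minus", p, DT, rng,
                                               n_ends=400, n_steps=6000)
        assert runs_plus.size > 2000 and runs_minus.size > 2000
        assert np.mean(runs_plus) == pytest.approx(12.0, rel=0.05)
        assert np.mean(runs_minus) == pytest.approx(3.0, rel=0.05)


class TestLengthRegulation:
    def test_stronger_feedback_restores_long_mts_faster(self):
        """The catastrophe slope gamma is a restoring force toward L0: for a
        population far above L0, larger gamma removes polymer faster."""
        masses = []
        for gamma in (0.01, 0.05):
            p = DynamicsParams(gamma=gamma, T_tot=np.inf)
            arr = make_array([(0.0, 2 * p.L0)] * 300, p)
            pool = TubulinPool(free=np.inf, total=np.inf)
            rng = np.random.default_rng(7)
            for _ in range(20 * 60):  # 20 min
                advance_end_states(arr, p, DT, rng)
                apply_polymerization(arr, pool, None, p, DT)
            masses.append((arr.upper - arr.lower)[arr.alive].sum())
        assert masses[1] < masses[0]

    def test_catastrophe_slope_cuts_both_ways(self, params):
        """Above L0 a larger gamma raises the catastrophe rate; below L0 it
        lowers it (down to the floor): the rate regulates length toward L0."""
        steep = DynamicsParams(gamma=0.05)
        assert catastrophe_rate(30.0, "plus", steep) > catastrophe_rate(
            30.0, "plus", params
        )
        assert catastrophe_rate(10.0, "plus", steep) < catastrophe_rate(
            10.0, "plus", params
        )
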