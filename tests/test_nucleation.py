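import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtpolarity import (
    CTRL_ENVIRONMENT,
    PAT_ENVIRONMENT,
    CheckpointEnvironment,
    CheckpointParams,
    LocalPolarityCount,
    Orientation,
    checkpoint_decision,
    meo_nucleation_probability,
    nucleate,
    proposed_checkpoint_success,
    simple_checkpoint_success,
    solve_autofail,
    solve_ns,
)


class TestFeedbackProbability:
    @pytest.mark.parametrize("n_plus,n_minus,feedback,expected", [
        (1, 3, True, 0.75),
        (0, 0, True, 0.5),    # empty site: coin flip
        (3, 7, False, 0.5),   # feedback off: coin flip regardless
        (5, 0, True, 0.0),
        (0, 4, True, 1.0),
    ])
    def test_local_composition_rule(self, n_plus, n_minus, feedback, expected):
        c = LocalPolarityCount(n_plus=n_plus, n_minus=n_minus)
        assert meo_nucleation_probability(c, feedback) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LocalPolarityCount(n_plus=-1, n_minus=0)


class TestNucleate:
    def test_peo_seed_above_site(self):
        mt = nucleate(30.0, Orientation.PEO, 0.1, domain_length=70.0)
        assert (mt.lower, mt.upper) == (30.0, 30.1)
        assert mt.plus_position == 30.1 and mt.minus_position == 30.0

    def test_meo_seed_below_site(self):
        mt = nucleate(30.0, Orientation.MEO, 0.1, domain_length=70.0)
        assert (mt.lower, mt.upper) == (29.9, 30.0)
        assert mt.plus_position == 29.9

    def test_seed_exiting_domain_rejected(self):
        with pytest.raises(ValueError, match="exits"):
            nucleate(0.05, Orientation.MEO, 0.1, domain_length=20.0)


class TestCheckpointDecision:
    def test_all_opposite_always_fails_without_autofail(self, rng):
        params = CheckpointParams(p_autofail=0.0)
        crossing = np.ones(10, dtype=bool)  # all MEO
        assert all(
            not checkpoint_decision(Orientation.PEO, crossing, params, rng)
            for _ in range(200)
        )

    def test_empty_site_passes_unless_autofail(self, rng):
        params = CheckpointParams(p_autofail=0.25)
        n = 20_000
        passes = sum(
            checkpoint_decision(Orientation.PEO, np.empty(0, bool), params, rng)
            for _ in range(n)
        )
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(passes / n - 0.75) < 3 * se

    def test_half_matching_pass_rate_matches_binomial(self, rng):
        """50% matching crossing set: pass ~ 1 - 0.5^6 = 0.984."""
        params = CheckpointParams(p_autofail=0.0, n_s=6)
        crossing = np.array([True, False] * 10)
        n = 100_000
        passes = sum(
            checkpoint_decision(Orientation.MEO, crossing, params, rng)
            for _ in range(n)
        )
        expected = 1.0 - 0.5**6
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(passes / n - expected) < 3 * se

    @pytest.mark.parametrize("env", [CTRL_ENVIRONMENT, PAT_ENVIRONMENT],
                             ids=["ctrl", "mixed"])
    @pytest.mark.parametrize("direction", list(Orientation))
    def test_monte_carlo_matches_analytic_model(self, env, direction, rng):
        """Crossing sets drawn from the environment reproduce the analytic
        success probability (growth factor removed) within 3 MC stderr."""
        params = CheckpointParams(p_autofail=0.25, n_s=6, baseline_exit=0.9)
        n_trials = 20_000
        # crossing sets large enough that their composition matches env
        crossing = rng.random((n_trials, 200)) < env.p_pre_meo
        expected = (
            proposed_checkpoint_success(env, direction, params)
            / params.baseline_exit
        )
        passes = sum(
            checkpoint_decision(direction, crossing[i], params, rng)
            for i in range(n_trials)
        )
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(passes / n_trials - expected) < 3 * se


class TestAnalyticModels:
    def test_simple_mechanism_printed_values(self):
        assert simple_checkpoint_success(
            CTRL_ENVIRONMENT, Orientation.PEO, 15, 0.9
        ) == pytest.approx(0.9 * (1 - 0.9**15))
        assert simple_checkpoint_success(
            CTRL_ENVIRONMENT, Orientation.MEO, 15, 0.9
        ) == pytest.approx(0.9 * (1 - 0.1**15))

    def test_simple_mechanism_no_opposition_limit(self):
        env = CheckpointEnvironment(p_pre_peo=0.0, p_pre_meo=1.0)
        assert simple_checkpoint_success(env, Orientation.MEO, 15, 0.9) == 0.9

    @pytest.mark.parametrize("direction,env,expected", [
        (Orientation.MEO, CTRL_ENVIRONMENT, 0.675 * (1 - 0.1**6)),
        (Orientation.PEO, CTRL_ENVIRONMENT, 0.675 * (1 - 0.9**6)),
        (Orientation.MEO, PAT_ENVIRONMENT, 0.675 * (1 - 0.5**6)),
        (Orientation.PEO, PAT_ENVIRONMENT, 0.675 * (1 - 0.5**6)),
    ])
    def test_two_step_mechanism_defaults(self, direction, env, expected):
        p = CheckpointParams(p_autofail=0.25, n_s=6, baseline_exit=0.9)
        assert proposed_checkpoint_success(env, direction, p) == pytest.approx(
            expected
        )

    def test_monotonicity_in_parameters(self):
        base = CheckpointParams(p_autofail=0.25, n_s=6, baseline_exit=0.9)
        env = CTRL_ENVIRONMENT
        up_ns = CheckpointParams(p_autofail=0.25, n_s=7, baseline_exit=0.9)
        up_af = CheckpointParams(p_autofail=0.30, n_s=6, baseline_exit=0.9)
        f = proposed_checkpoint_success
        assert f(env, Orientation.PEO, up_ns) > f(env, Orientation.PEO, base)
        assert f(env, Orientation.PEO, up_af) < f(env, Orientation.PEO, base)
        # higher opposition lowers success
        worse = CheckpointEnvironment(p_pre_peo=0.05, p_pre_meo=0.95)
        assert f(worse, Orientation.PEO, base) < f(env, Orientation.PEO, base)


class TestCalibrationSolvers:
    def test_autofail_from_printed_rates(self):
        raw, rounded = solve_autofail(0.66, 0.9)
        assert raw == pytest.approx(1 - 0.66 / 0.9)
        assert rounded == 0.25

    def test_autofail_edge_cases(self):
        assert solve_autofail(0.9, 0.9)[0] == 0.0
        assert solve_autofail(0.45, 0.9)[0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            solve_autofail(0.95, 0.9)

    def test_ns_from_printed_rates(self):
        raw, rounded = solve_ns(0.66, 0.9, 0.25, 0.5)
        assert raw == pytest.approx(5.4919, abs=1e-3)
        assert rounded == 6

    def test_ns_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_ns(0.7, 0.9, 0.25, 0.5)  # exceeds 0.675 ceiling
        with pytest.raises(ValueError):
            solve_ns(0.5, 0.9, 0.25, 1.0)

    @given(
        p_autofail=st.floats(0.0, 0.9),
        n_s=st.integers(1, 12),
        p_opp=st.floats(0.1, 0.9),
    )
    @settings(deadline=None, max_examples=200)
    def test_solvers_invert_forward_model(self, p_autofail, n_s, p_opp):
        """Round trip through the forward model recovers the parameters."""
        baseline = 0.9
        env = CheckpointEnvironment(p_pre_peo=p_opp, p_pre_meo=1 - p_opp)
        params = CheckpointParams(p_autofail=p_autofail, n_s=n_s,
                                  baseline_exit=baseline)
        observed = proposed_checkpoint_success(env, Orientation.MEO, params)
        # invert for n_s given the true autofail
        raw_ns, _ = solve_ns(observed, baseline, p_autofail, p_opp)
        # p_opp**n_s can sit near float cancellation; the root is recovered
        # to the precision the forward probability retains
        assert raw_ns == pytest.approx(n_s, abs=1e-4)
        # invert for autofail in the saturated-sampling regime
        sat = CheckpointEnvironment(p_pre_peo=1e-9, p_pre_meo=1 - 1e-9)
        obs2 = proposed_checkpoint_success(sat, Orientation.MEO, params)
        raw_af, _ = solve_autofail(obs2, baseline)
        assert raw_af == pytest.approx(p_autofail, abs=1e-6)
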