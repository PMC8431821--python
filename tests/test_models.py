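"""Forward-model dynamics against closed-form oracles and limit cases."""

import numpy as np
import pytest

from stridelearn.models import (
    ABParams,
    ModABParams,
    ModSUParams,
    SUParams,
    map_estimate,
    posterior_variance,
    simulate_ab,
    simulate_ab_states,
    simulate_modified_ab,
    simulate_modified_su,
    simulate_su,
    simulate_su_states,
)
from stridelearn.schedules import make_schedule


def su_fixed_point(p: SUParams, t: float, gamma: float = 1.0):
    """Independent oracle: solve the 2x2 steady-state linear system."""
    # s (1 - A + C) + C w = C t ;  -gamma F s + (1 - E - gamma F) w = 0
    M = np.array([[1 - p.A + p.C, p.C], [-gamma * p.F, 1 - p.E - gamma * p.F]])
    s, w = np.linalg.solve(M, [p.C * t, 0.0])
    return s, w, s + w


class TestStrategyPlusUseDependent:
    def test_parameter_constraints(self):
        with pytest.raises(ValueError, match="5x"):
            SUParams(A=0.9, C=0.1, F=0.05, E=0.9)
        with pytest.raises(ValueError, match="A="):
            SUParams(A=1.2, C=0.5, F=0.01, E=0.9)

    def test_zero_use_dependent_rate_gives_zero_washout(self, constant_schedule):
        # F -> 0 limit: w never departs 0 and s=0 without feedback
        p = SUParams(A=0.99, C=0.46, F=1e-12, E=0.95)
        x = simulate_su(p, constant_schedule)
        w = x[constant_schedule.mask("washout")]
        assert np.abs(w).max() < 1e-7

    def test_first_strategic_update_is_C_times_target(self, su_params, constant_schedule):
        # zero state at learning onset: one iteration gives output C * 22
        x = simulate_su(su_params, constant_schedule)
        n0 = int(np.flatnonzero(constant_schedule.mask("learning"))[0])
        assert x[n0] == 0.0
        assert x[n0 + 1] == pytest.approx(0.46 * 22.0, abs=1e-12)

    @pytest.mark.parametrize("gamma", [1.0, 0.76, 0.53])
    def test_washout_decay_factor_is_E_plus_gamma_F(self, su_params, constant_schedule, gamma):
        x = simulate_su(su_params, constant_schedule, gamma=gamma)
        w = x[constant_schedule.mask("washout")]
        rate = su_params.E + gamma * su_params.F
        np.testing.assert_allclose(w[1:], rate * w[:-1], rtol=0, atol=1e-9)

    def test_constant_target_fixed_point(self, su_params):
        # long all-feedback run converges to the linear-solve steady state
        sched = make_schedule("constant", 0, 5000, 0, seed=0)
        x = simulate_su(su_params, sched)
        _, _, x_star = su_fixed_point(su_params, 22.0)
        assert abs(x[-1] - x_star) < 1e-6

    def test_washout_monotone_decay_to_zero(self, su_params, constant_schedule):
        x = simulate_su(su_params, constant_schedule)
        w = x[constant_schedule.mask("washout")]
        assert (np.diff(w) <= 0).all() and w[-1] >= 0


class TestAdaptiveBayesian:
    def test_equal_variances_give_midpoint(self):
        assert map_estimate(10.0, 5.0, 20.0, 5.0) == pytest.approx(15.0)

    def test_posterior_variance_harmonic(self):
        assert posterior_variance(2.0, 2.0) == pytest.approx(1.0)
        s2 = posterior_variance(63.9, 17.0)
        assert s2 <= min(63.9, 17.0)

    def test_beta_one_full_update(self):
        # beta = 1: prior mean jumps to the target; prior variance = (mean - target)^2
        p = ABParams(beta=1 - 1e-12, sigma2_lik=10.0)
        sched = make_schedule("constant", 2, 3, 2, seed=0)
        x = simulate_ab(p, sched)
        # stride 3 is the second learning stride: prior mean was set to 22
        # on the first learning stride, so the MAP blends 22 with theta=22.
        assert x[3] == pytest.approx(22.0, abs=1e-6)

    def test_map_is_convex_combination(self, rng):
        theta_bar = rng.uniform(-50, 50, 10_000)
        theta = rng.uniform(-50, 50, 10_000)
        s2p = rng.uniform(1e-6, 200, 10_000)
        s2l = rng.uniform(1e-3, 100, 10_000)
        m = map_estimate(theta_bar, s2p, theta, s2l)
        lo = np.minimum(theta_bar, theta)
        hi = np.maximum(theta_bar, theta)
        assert (m >= lo - 1e-9).all() and (m <= hi + 1e-9).all()

    def test_output_bounded_by_targets(self, ab_params, schedules_by_condition):
        # every output is a blend of prior mean and target, both in [0, 39]
        for sched in schedules_by_condition.values():
            x = simulate_ab(ab_params, sched)
            assert x.min() >= -1e-9 and x.max() <= 39.0 + 1e-9


class TestModifiedModels:
    def test_gamma_one_limit_reduces_to_su(self, su_params, schedules_by_condition):
        p = ModSUParams(
            A=su_params.A, C=su_params.C, F=su_params.F, E=su_params.E,
            gamma_LV=1 - 1e-12, gamma_HV=1 - 2e-12,
        )
        for sched in schedules_by_condition.values():
            np.testing.assert_allclose(
                simulate_modified_su(p, sched), simulate_su(su_params, sched), atol=1e-9
            )

    def test_initial_bias_ordered_by_gain(self, mod_su_params, schedules_by_condition):
        bias = {}
        for cond, sched in schedules_by_condition.items():
            x = simulate_modified_su(mod_su_params, sched)
            bias[cond] = x[sched.mask("washout")][:5].mean()
        assert bias["constant"] > bias["LV"] > bias["HV"]

    def test_modified_su_washout_decay_per_condition(self, mod_su_params, schedules_by_condition):
        for cond, sched in schedules_by_condition.items():
            x = simulate_modified_su(mod_su_params, sched)
            w = x[sched.mask("washout")]
            rate = mod_su_params.E + mod_su_params.gamma(cond) * mod_su_params.F
            np.testing.assert_allclose(w[1:], rate * w[:-1], rtol=0, atol=1e-9)

    def test_equal_pairs_reduce_to_ab(self, ab_params, schedules_by_condition):
        p = ModABParams(
            beta_vf=ab_params.beta, sigma2_vf=ab_params.sigma2_lik,
            beta_novf=ab_params.beta, sigma2_novf=ab_params.sigma2_lik,
        )
        for sched in schedules_by_condition.values():
            np.testing.assert_allclose(
                simulate_modified_ab(p, sched), simulate_ab(ab_params, sched), atol=0
            )

    def test_washout_prior_geometric_decay(self, mod_ab_params, constant_schedule):
        # with theta=0 the prior mean decays by exactly (1 - beta_novf) per stride
        st = simulate_ab_states(mod_ab_params, constant_schedule)
        tb = st["theta_bar"][constant_schedule.mask("washout")]
        np.testing.assert_allclose(
            tb[1:], (1 - mod_ab_params.beta_novf) * tb[:-1], rtol=1e-12
        )

    def test_ab_state_invariants(self, ab_params, mod_ab_params, schedules_by_condition):
        # prior variance floored positive; posterior variance below both sources
        for sched in schedules_by_condition.values():
            for p, s2_lik in ((ab_params, None), (mod_ab_params, None)):
                st = simulate_ab_states(p, sched)
                assert (st["sigma2_prior"] > 0).all()
                assert (st["sigma2_post"] <= st["sigma2_prior"] + 1e-12).all()

    def test_su_output_is_sum_of_components(self, su_params, schedules_by_condition):
        for sched in schedules_by_condition.values():
            st = simulate_su_states(su_params, sched)
            np.testing.assert_allclose(st["x"], st["s"] + st["w"], atol=0)
            # strategy is identically zero off-feedback
            assert np.abs(st["s"][~sched.vf]).max() == 0.0

    def test_frozen_prior_when_beta_novf_tiny(self, constant_schedule):
        p = ModABParams(beta_vf=0.2, sigma2_vf=78.86, beta_novf=1e-9, sigma2_novf=2.05)
        st = simulate_ab_states(p, constant_schedule)
        wmask = constant_schedule.mask("washout")
        tb = st["theta_bar"][wmask]
        # drift bounded by beta * n_washout * theta_bar
        assert np.ptp(tb) < 1e-9 * tb.size * tb[0] * 1.01
        w = st["x"][wmask]
        assert abs(w[-1] - w[5]) < 1e-2  # output held at the prior/likelihood blend

    def test_ordinal_gain_constraint(self):
        with pytest.raises(ValueError, match="gamma"):
            ModSUParams(A=0.9, C=0.5, F=1e-3, E=0.9, gamma_LV=0.5, gamma_HV=0.7)


def test_simulators_deterministic(su_params, ab_params, schedules_by_condition):
    for sched in schedules_by_condition.values():
        np.testing.assert_array_equal(
            simulate_su(su_params, sched), simulate_su(su_params, sched)
        )
        np.testing.assert_array_equal(
            simulate_ab(ab_params, sched), simulate_ab(ab_params, sched)
        )
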