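"""Lesion-kinetics engine: PLL profiles, per-fraction coefficients, yields."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from imksurv import (
    CellStateTrajectory,
    ConfigurationError,
    DataValidationError,
    DoseSchedule,
    IMKParameters,
    lethal_lesion_yield,
    pll_profile,
    state_coefficients,
    survival,
)


def constant_traj(n, c=0.704):
    return CellStateTrajectory.constant(n, c)


class TestPLLProfile:
    def test_initial_condition_single_fraction(self, plateau):
        sch = DoseSchedule((1.0,), 1.0)
        assert pll_profile(0.0, sch, constant_traj(1), plateau) == pytest.approx(1.0)

    def test_e_folding_time(self, plateau):
        sch = DoseSchedule((1.0,), 1.0)
        t = 1.0 / 0.704
        val = pll_profile(t, sch, constant_traj(1), plateau)
        assert val == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_two_fraction_jump(self, plateau):
        # right-continuous at the second impulse: e^{-0.352} + 1
        sch = DoseSchedule((1.0, 1.0), 0.5)
        val = pll_profile(0.5, sch, constant_traj(2), plateau)
        assert val == pytest.approx(math.exp(-0.352) + 1.0, rel=1e-12)
        assert val == pytest.approx(1.7033, abs=5e-5)

    def test_decays_between_fractions(self, plateau):
        sch = DoseSchedule((1.0, 1.0), 0.5)
        traj = constant_traj(2)
        ts = np.linspace(0.0, 0.499, 50)
        vals = pll_profile(ts, sch, traj, plateau)
        assert np.all(np.diff(vals) < 0)

    def test_matches_cohort_ode_oracle(self, plateau):
        # each fraction's cohort obeys dx/dt = -(a+c_n) x from its impulse;
        # integrate numerically and compare with the closed-form profile
        rng = np.random.default_rng(42)
        for _ in range(3):
            n = int(rng.integers(2, 6))
            doses = tuple(rng.uniform(0.2, 2.0, n))
            dt = float(rng.uniform(0.2, 1.0))
            g = tuple(rng.uniform(0.8, 1.4, n))
            c = tuple(rng.uniform(0.3, 2.0, n))
            traj = CellStateTrajectory(g, tuple(v**2 for v in g), c)
            sch = DoseSchedule(doses, dt)
            t_query = float(rng.uniform(0, n * dt + 1.0))
            oracle = 0.0
            for k in range(n):
                t_k = k * dt
                if t_query < t_k:
                    continue
                sol = solve_ivp(
                    lambda t, x, r=c[k]: -r * x,
                    (t_k, max(t_query, t_k + 1e-12)),
                    [g[k] * doses[k]],
                    rtol=1e-12,
                    atol=1e-14,
                )
                oracle += sol.y[0, -1]
            val = pll_profile(t_query, sch, traj, plateau)
            assert val == pytest.approx(oracle, rel=1e-8)

    def test_negative_time_rejected(self, plateau):
        sch = DoseSchedule((1.0,), 1.0)
        with pytest.raises(DataValidationError):
            pll_profile(-0.1, sch, constant_traj(1), plateau)

    def test_length_mismatch_rejected(self, plateau):
        sch = DoseSchedule((1.0, 1.0), 1.0)
        with pytest.raises(ConfigurationError):
            pll_profile(0.0, sch, constant_traj(3), plateau)


class TestStateCoefficients:
    def test_constant_state_reduces_to_baseline(self, plateau):
        traj = constant_traj(3, plateau.sldr_rate0)
        a, b, bnm = state_coefficients(1, 2, traj, plateau)
        assert a == pytest.approx(plateau.alpha0, rel=1e-14)
        assert b == pytest.approx(plateau.beta0, rel=1e-14)
        assert bnm == pytest.approx(plateau.beta0, rel=1e-14)

    def test_plateau_to_log_alpha(self, plateau):
        # state with log-phase DNA and repair: alpha drops to ~0.075 /Gy
        traj = CellStateTrajectory((1.0, 1.227), (1.0, 1.457), (0.704, 1.782))
        _, _, _ = state_coefficients(1, 2, traj, plateau)
        a2 = plateau.alpha0 * 1.227 * 0.704 / 1.782
        traj2 = CellStateTrajectory((1.227, 1.0), (1.457, 1.0), (1.782, 0.704))
        a_n, b_n, _ = state_coefficients(1, 2, traj2, plateau)
        assert a_n == pytest.approx(a2, rel=1e-14)
        assert a_n == pytest.approx(0.075, abs=5e-4)
        assert b_n == pytest.approx(0.028, abs=5e-4)

    def test_index_order_enforced(self, plateau):
        traj = constant_traj(3)
        with pytest.raises(ConfigurationError):
            state_coefficients(2, 2, traj, plateau)
        with pytest.raises(ConfigurationError):
            state_coefficients(0, 1, traj, plateau)

    def test_nonpositive_rate_rejected_at_construction(self):
        with pytest.raises(DataValidationError):
            CellStateTrajectory((1.0,), (1.0,), (0.0,))


class TestLethalLesionYield:
    def test_zero_dose_gives_full_survival(self, plateau):
        sch = DoseSchedule((0.0, 0.0), 1.0)
        tally = lethal_lesion_yield(sch, constant_traj(2), plateau)
        assert tally.w_mean == 0.0
        assert tally.survival == 1.0

    def test_single_fraction_acute_lq(self, plateau):
        sch = DoseSchedule((2.0,), 1.0)
        tally = lethal_lesion_yield(sch, constant_traj(1), plateau)
        expected = (0.155 + 0.924 * 0.048) * 2.0 + 0.048 * 4.0
        assert tally.w_mean == pytest.approx(expected, rel=1e-12)
        assert tally.survival == pytest.approx(0.554, abs=5e-4)

    def test_two_fraction_hand_value(self, plateau):
        sch = DoseSchedule((1.5, 1.5), 0.5)
        tally = lethal_lesion_yield(sch, constant_traj(2), plateau)
        expected = 0.598056 + 0.216 + 0.216 * math.exp(-0.352)
        assert tally.w_mean == pytest.approx(expected, rel=1e-12)
        assert tally.w_mean == pytest.approx(0.9660, abs=5e-5)

    def test_terms_sum_to_w_mean(self, plateau):
        sch = DoseSchedule((1.0, 2.0, 0.5), 0.4)
        traj = CellStateTrajectory(
            (1.0, 1.1, 1.2), (1.0, 1.21, 1.44), (0.704, 1.0, 1.5)
        )
        tally = lethal_lesion_yield(sch, traj, plateau)
        assert tally.linear + tally.quadratic + tally.cross == tally.w_mean
        assert tally.linear >= 0 and tally.quadratic >= 0 and tally.cross >= 0

    def test_general_cross_term_matches_bruteforce(self, plateau):
        # independent O(N^2) evaluation of the double sum over fraction pairs
        rng = np.random.default_rng(7)
        n = 17
        doses = tuple(rng.uniform(0.1, 1.5, n))
        g = tuple(rng.uniform(0.8, 1.4, n))
        c = tuple(rng.uniform(0.3, 2.5, n))
        dt = 0.35
        traj = CellStateTrajectory(g, tuple(v**2 for v in g), c)
        sch = DoseSchedule(doses, dt)
        r1 = plateau.repair_rate0
        cross = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                bnm = plateau.beta0 * g[i] * g[j] * 2 * r1 / (c[i] + c[j])
                cross += bnm * math.exp(-(j - i) * c[i] * dt) * doses[i] * doses[j]
        tally = lethal_lesion_yield(sch, traj, plateau)
        assert tally.cross == pytest.approx(2 * cross, rel=1e-12)

    def test_constant_rate_fast_path_matches_general(self, plateau):
        # same schedule evaluated through the O(N) recurrence and the O(N^2)
        # matrix path (forced by a negligible rate perturbation)
        rng = np.random.default_rng(11)
        n = 40
        doses = tuple(rng.uniform(0.1, 1.0, n))
        g = tuple(rng.uniform(0.9, 1.3, n))
        traj_const = CellStateTrajectory(g, tuple(v**2 for v in g), (0.9,) * n)
        c_perturbed = (0.9,) * (n - 1) + (0.9 * (1 + 1e-13),)
        traj_pert = CellStateTrajectory(g, tuple(v**2 for v in g), c_perturbed)
        sch = DoseSchedule(doses, 0.25)
        w1 = lethal_lesion_yield(sch, traj_const, plateau).w_mean
        w2 = lethal_lesion_yield(sch, traj_pert, plateau).w_mean
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_cross_rate_mean_mode_differs_only_with_varying_rates(self, plateau):
        sch = DoseSchedule((1.0, 1.0), 0.5)
        traj = CellStateTrajectory((1.0, 1.0), (1.0, 1.0), (0.5, 2.0))
        w_earlier = lethal_lesion_yield(sch, traj, plateau).w_mean
        w_mean = lethal_lesion_yield(sch, traj, plateau, cross_rate="mean").w_mean
        assert w_earlier != w_mean
        tconst = constant_traj(2)
        assert lethal_lesion_yield(sch, tconst, plateau).w_mean == pytest.approx(
            lethal_lesion_yield(sch, tconst, plateau, cross_rate="mean").w_mean,
            rel=1e-14,
        )

    def test_nan_dose_rejected(self, plateau):
        with pytest.raises(DataValidationError):
            DoseSchedule((1.0, float("nan")), 0.5)


class TestSurvival:
    def test_zero_dose(self, plateau):
        assert survival(DoseSchedule((0.0,), 1.0), params=plateau) == 1.0

    def test_dose_escalation_never_increases_survival(self, plateau):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(1, 6))
            doses = rng.uniform(0.0, 2.0, n)
            dt = float(rng.uniform(0.1, 2.0))
            s1 = survival(DoseSchedule(tuple(doses), dt), params=plateau)
            s2 = survival(DoseSchedule(tuple(2 * doses), dt), params=plateau)
            assert s2 <= s1

    def test_splitting_a_fraction_never_decreases_survival(self, plateau):
        # repair between the halves can only spare
        whole = survival(DoseSchedule((4.0,), 0.5), params=plateau)
        split = survival(DoseSchedule((2.0, 2.0), 0.5), params=plateau)
        assert split >= whole

    def test_survival_in_unit_interval(self, plateau):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(1, 8))
            sch = DoseSchedule(tuple(rng.uniform(0, 5, n)), float(rng.uniform(0.1, 2)))
            s = survival(sch, params=plateau)
            assert 0.0 < s <= 1.0

    def test_extreme_dose_underflows_to_zero_with_warning(self, plateau):
        sch = DoseSchedule((200.0,), 1.0)
        with pytest.warns(RuntimeWarning):
            s = survival(sch, params=plateau)
        assert s == 0.0


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha0=-0.1, beta0=0.05, repair_rate0=0.7, gamma=0.9),
            dict(alpha0=0.1, beta0=-0.05, repair_rate0=0.7, gamma=0.9),
            dict(alpha0=0.1, beta0=0.05, repair_rate0=0.0, gamma=0.9),
            dict(alpha0=0.1, beta0=0.05, repair_rate0=0.7, gamma=-0.9),
            dict(alpha0=0.1, beta0=0.05, repair_rate0=0.7, gamma=0.9, a_rate=0.8),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DataValidationError):
            IMKParameters(**kwargs)

    def test_schedule_validation(self):
        with pytest.raises(DataValidationError):
            DoseSchedule((), 1.0)
        with pytest.raises(DataValidationError):
            DoseSchedule((1.0,), 0.0)
        with pytest.raises(DataValidationError):
            DoseSchedule((-1.0,), 1.0)
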