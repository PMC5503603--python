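"""Forward model: closed forms against analytic identities and ODE oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from raitg import (
    DoseEvent,
    IndividualParameters,
    Regimen,
    activity_at,
    activity_integral,
    simulate_observations,
    tg_trajectory,
    tumor_at,
)
from raitg.model_core import LN2

from conftest import ode_oracle, random_instance


class TestActivity:
    def test_initial_condition(self, single_dose):
        assert activity_at(0.0, single_dose, a=0.0169) == pytest.approx(3.7)

    def test_half_life_identity(self, single_dose):
        # the decay law halves the activity after 1/a months
        assert activity_at(1 / 0.0169, single_dose, a=0.0169) == pytest.approx(3.7 / 2)

    def test_closed_form_at_12_months(self, single_dose):
        expected = 3.7 * 2 ** (-0.0169 * 12)
        assert activity_at(12.0, single_dose, a=0.0169) == pytest.approx(expected, rel=1e-12)
        oracle = ode_oracle(
            IndividualParameters(rho=1e-3, a=0.0169, lam=1e-9, ke=0.3, Td=10, N0=1e9),
            single_dose,
            [12.0],
            tg0=1.0,
        )
        assert activity_at(12.0, single_dose, a=0.0169) == pytest.approx(
            oracle["activity"][0], rel=1e-8
        )

    def test_zero_before_first_dose_contribution(self):
        reg = Regimen((DoseEvent(0.0, 3.7), DoseEvent(10.0, 5.0)))
        # just before the second dose only the first contributes
        assert activity_at(9.999, reg, a=0.1) == pytest.approx(
            3.7 * 2 ** (-0.1 * 9.999)
        )

    def test_negative_time_rejected(self, single_dose):
        with pytest.raises(ValueError):
            activity_at(-1.0, single_dose, a=0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.005, 0.2),
        act1=st.floats(3.7, 5.5),
        act2=st.floats(3.7, 5.5),
        gap=st.floats(1.0, 12.0),
        t=st.floats(0.0, 60.0),
    )
    def test_superposition(self, a, act1, act2, gap, t):
        """A two-dose regimen is the sum of its single-dose parts."""
        both = Regimen((DoseEvent(0.0, act1), DoseEvent(gap, act2)))
        first = Regimen.single(act1)
        expected = activity_at(t, first, a)
        if t >= gap:
            expected += act2 * 2 ** (-a * (t - gap))
        assert activity_at(t, both, a) == pytest.approx(expected, rel=1e-12)


class TestActivityIntegral:
    def test_empty_interval(self, single_dose):
        assert activity_integral(5.0, 5.0, single_dose, a=0.1) == 0.0

    def test_infinite_horizon_limit(self, single_dose):
        # ∫_0^∞ A0·2^(-a t) dt = A0/(a ln2)
        assert activity_integral(0.0, 1e7, single_dose, a=0.0169) == pytest.approx(
            3.7 / (0.0169 * LN2), rel=1e-9
        )

    def test_against_quadrature_oracle(self):
        reg = Regimen((DoseEvent(0.0, 3.7), DoseEvent(7.0, 5.5)))
        a = 0.05
        val, _ = quad(lambda s: activity_at(s, reg, a), 2.0, 20.0, points=[7.0], limit=200)
        assert activity_integral(2.0, 20.0, reg, a) == pytest.approx(val, rel=1e-9)

    def test_additive_over_subintervals(self, single_dose):
        a = 0.0169
        whole = activity_integral(0.0, 30.0, single_dose, a)
        split = activity_integral(0.0, 11.0, single_dose, a) + activity_integral(
            11.0, 30.0, single_dose, a
        )
        assert whole == pytest.approx(split, rel=1e-12)

    def test_reversed_bounds_rejected(self, single_dose):
        with pytest.raises(ValueError):
            activity_integral(5.0, 1.0, single_dose, a=0.1)


class TestTumor:
    def test_initial_condition(self, median_params, single_dose):
        assert tumor_at(0.0, median_params, single_dose) == median_params.N0

    def test_pure_doubling(self, single_dose):
        # with a vanishing kill term the count doubles every Td
        p = IndividualParameters(rho=1e-15, a=0.0169, lam=1e-9, ke=0.3, Td=9.8, N0=1e9)
        assert tumor_at(9.8, p, single_dose) == pytest.approx(2e9, rel=1e-6)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_doubling_identity(self, k, single_dose):
        p = IndividualParameters(rho=1e-15, a=0.0169, lam=1e-9, ke=0.3, Td=7.0, N0=5e8)
        assert tumor_at(k * 7.0, p, single_dose) == pytest.approx(
            2**k * 5e8, rel=1e-6
        )

    def test_against_ode_oracle(self, median_params, single_dose):
        oracle = ode_oracle(median_params, single_dose, [6.0], tg0=1.0)
        assert tumor_at(6.0, median_params, single_dose) == pytest.approx(
            oracle["tumor"][0], rel=1e-6
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rho_lo=st.floats(1e-4, 5e-3),
        factor=st.floats(1.5, 10.0),
        t=st.floats(0.5, 50.0),
    )
    def test_monotone_in_rho(self, rho_lo, factor, t):
        """A more efficient kill never leaves more cells."""
        regimen = Regimen.single(3.7)
        base = dict(a=0.0169, lam=1e-9, ke=0.3, Td=9.8, N0=1e9)
        lo = IndividualParameters(rho=rho_lo, **base)
        hi = IndividualParameters(rho=rho_lo * factor, **base)
        assert tumor_at(t, hi, regimen) <= tumor_at(t, lo, regimen)


class TestTgTrajectory:
    def test_pure_elimination(self, single_dose):
        # without production Tg decays exponentially at rate ke
        p = IndividualParameters(rho=1e-3, a=0.0169, lam=1e-30, ke=0.319, Td=9.8, N0=1e9)
        t = np.array([0.0, 3.0, 9.0])
        tg = tg_trajectory(t, p, single_dose, tg0=20.0)
        assert np.allclose(tg, 20.0 * np.exp(-0.319 * t), rtol=1e-7)

    def test_steady_state_limit(self, single_dose):
        # constant tumor (huge Td, vanishing kill): Tg settles at lam*N0/ke
        p = IndividualParameters(rho=1e-15, a=0.0169, lam=3.86e-9, ke=0.319, Td=1e9, N0=1.12e9)
        tg = tg_trajectory([150.0], p, single_dose, tg0=0.0)
        assert tg[0] == pytest.approx(p.lam * p.N0 / p.ke, rel=1e-5)

    def test_against_ode_oracle_at_study_medians(self, median_params, single_dose):
        tg0 = median_params.steady_state_tg
        times = [0.0, 6.0, 12.0, 18.0]
        ours = tg_trajectory(times, median_params, single_dose, tg0)
        oracle = ode_oracle(median_params, single_dose, times, tg0)
        assert np.allclose(ours, oracle["tg"], rtol=1e-5)

    def test_unsorted_times_rejected(self, median_params, single_dose):
        with pytest.raises(ValueError):
            tg_trajectory([5.0, 1.0], median_params, single_dose, 10.0)

    def test_nonnegative_everywhere(self, median_params):
        reg = Regimen.evenly_spaced(5, 5.5, 6.0)
        t = np.linspace(0, 40, 81)
        tg = tg_trajectory(t, median_params, reg, tg0=0.0)
        assert np.all(tg >= 0)


class TestForwardOracleSweep:
    def test_random_instances_match_ode(self):
        """Semi-analytic A(t), N(t), Tg(t) against brute-force integration on
        randomized parameters and regimens."""
        rng = np.random.default_rng(20240)
        for _ in range(20):
            p, regimen = random_instance(rng)
            t_end = float(regimen.times[-1]) + 10.0
            times = np.sort(rng.uniform(0.5, t_end, size=4))
            tg0 = p.steady_state_tg
            oracle = ode_oracle(p, regimen, times, tg0)
            a_ours = activity_at(times, regimen, p.a)
            n_ours = tumor_at(times, p, regimen)
            tg_ours = tg_trajectory(times, p, regimen, tg0)
            assert np.allclose(a_ours, oracle["activity"], rtol=1e-6)
            assert np.allclose(n_ours, oracle["tumor"], rtol=1e-6)
            assert np.allclose(tg_ours, oracle["tg"], rtol=1e-5)


class TestSimulateObservations:
    def test_no_noise_returns_trajectory(self, median_params, single_dose):
        times = [0.0, 6.0, 12.0]
        sim = simulate_observations(median_params, single_dose, times, b=0.0, rng=1)
        assert np.array_equal(
            sim.values,
            tg_trajectory(times, median_params, single_dose, median_params.steady_state_tg),
        )
        assert not sim.truncated.any()

    def test_seed_contract(self, median_params, single_dose):
        times = [0.0, 6.0, 12.0]
        s1 = simulate_observations(median_params, single_dose, times, 0.372, rng=7)
        s2 = simulate_observations(median_params, single_dose, times, 0.372, rng=7)
        s3 = simulate_observations(median_params, single_dose, times, 0.372, rng=8)
        assert np.array_equal(s1.values, s2.values)
        assert not np.array_equal(s1.values, s3.values)

    def test_error_model_is_mean_one_proportional(self, median_params, single_dose):
        """Monte-Carlo check: E[y/f] = 1 under y = f(1 + b·eps)."""
        n = 10**5
        rng = np.random.default_rng(3)
        f = tg_trajectory([6.0], median_params, single_dose, median_params.steady_state_tg)[0]
        draws = np.empty(n)
        eps = rng.standard_normal(n)
        draws = f * (1 + 0.372 * eps)
        ratio = draws / f
        se = 0.372 / math.sqrt(n)
        assert abs(ratio.mean() - 1.0) < 3 * se

    def test_truncation_flags_negative_draws(self, median_params, single_dose):
        rng = np.random.default_rng(0)
        sim = simulate_observations(
            median_params, single_dose, np.full(2000, 6.0), b=0.372, rng=rng
        )
        assert sim.truncated.any()
        assert np.all(sim.values >= 0)
        assert np.all(sim.values[sim.truncated] == 0.0)


class TestInvariants:
    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 3.7)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.0)

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            Regimen(())
        with pytest.raises(ValueError):
            Regimen((DoseEvent(0.0, 3.7), DoseEvent(0.0, 3.7)))
        with pytest.raises(ValueError):
            Regimen((DoseEvent(1.0, 3.7),))  # first dose must set t=0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            IndividualParameters(rho=0, a=0.01, lam=1e-9, ke=0.3, Td=10, N0=1e9)
        with pytest.raises(ValueError):
            IndividualParameters(rho=1e-3, a=0.01, lam=1e-9, ke=0.3, Td=10, N0=0.5)
        with pytest.raises(ValueError):
            IndividualParameters(
                rho=1e-3, a=0.01, lam=1e-9, ke=0.3, Td=10, N0=1e9, category=3
            )
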