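"""Unit and property tests for the compartment-model kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pausekinetics import kinetics as K
from pausekinetics.errors import (
    DegenerateSteadyStateError,
    InvalidParameterError,
    UnscaledDensityError,
)
from pausekinetics.kinetics import Boundary, RateSet

positive_rate = st.floats(1e-3, 1e3)
fold = st.floats(1e-2, 1e2)


class TestSteadyState:
    def test_unit_rates(self):
        ss = K.steady_state(RateSet(1, 0, 1, 1))
        assert ss.p == 1 and ss.b == 1

    def test_representative_gene(self, fig_rates):
        ss = K.steady_state(fig_rates)
        assert ss.p == pytest.approx(0.25641, rel=1e-4)
        assert ss.b == pytest.approx(3.2051e-5, rel=1e-4)

    def test_linearity_in_initiation(self, fig_rates):
        ss = K.steady_state(fig_rates)
        doubled = K.steady_state(
            RateSet(2 * fig_rates.k_init, fig_rates.k_pre,
                    fig_rates.k_rel, fig_rates.k_elong)
        )
        assert doubled.p == pytest.approx(2 * ss.p)
        assert doubled.b == pytest.approx(2 * ss.b)

    def test_zero_exit_rate_raises(self):
        with pytest.raises(DegenerateSteadyStateError):
            K.steady_state(RateSet(1, 0, 0, 1))

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            RateSet(-1, 0, 1, 1)


class TestOde:
    def test_no_flux_is_constant(self):
        t, p, b = K.simulate_ode(RateSet(0, 0, 0, 0), 0.3, 0.1, 10, 1)
        assert np.allclose(p, 0.3) and np.allclose(b, 0.1)

    def test_converges_to_steady_state(self, fig_rates):
        ss = K.steady_state(fig_rates)
        _, p, b = K.simulate_ode(fig_rates, 0, 0, 60, 0.5)
        assert p[-1] == pytest.approx(ss.p, rel=1e-6)
        assert b[-1] == pytest.approx(ss.b, rel=1e-6)

    def test_pure_decay_when_initiation_off(self, fig_rates):
        p_ss = K.steady_state(fig_rates).p
        rates = RateSet(0, fig_rates.k_pre, fig_rates.k_rel, fig_rates.k_elong)
        t, p, _ = K.simulate_ode(rates, p_ss, 0, 3, 0.25)
        expected = p_ss * np.exp(-rates.k_exit * t)
        assert np.allclose(p, expected, rtol=1e-9)

    def test_matches_numeric_integration(self, rng):
        rates = RateSet(*rng.uniform(0.1, 3.0, 3), k_elong=rng.uniform(500, 3000))
        t, p, b = K.simulate_ode(rates, 0.7, 1e-4, 5, 0.5)
        sol = solve_ivp(
            lambda _, y: [rates.k_init - rates.k_exit * y[0],
                          rates.k_rel * y[0] - rates.k_elong * y[1]],
            (0, 5), [0.7, 1e-4], t_eval=t, rtol=1e-10, atol=1e-14,
        )
        assert np.allclose(p, sol.y[0], rtol=1e-6)
        assert np.allclose(b, sol.y[1], rtol=1e-6, atol=1e-12)

    def test_invalid_inputs(self, fig_rates):
        with pytest.raises(InvalidParameterError):
            K.simulate_ode(fig_rates, -0.1, 0, 1, 0.1)
        with pytest.raises(InvalidParameterError):
            K.simulate_ode(fig_rates, 0, 0, 0, 0.1)

    @settings(derandomize=True, max_examples=30)
    @given(k_init=positive_rate, k_pre=positive_rate, k_rel=positive_rate)
    def test_any_start_converges(self, k_init, k_pre, k_rel):
        rates = RateSet(k_init, k_pre, k_rel, 1000.0)
        ss = K.steady_state(rates)
        horizon = 45.0 * max(1.0 / rates.k_exit, 1.0 / rates.k_elong)
        _, p, b = K.simulate_ode(rates, 5 * ss.p + 1, 3 * ss.b + 1,
                                 horizon, horizon / 50)
        assert p[-1] == pytest.approx(ss.p, rel=1e-6, abs=1e-12)
        assert b[-1] == pytest.approx(ss.b, rel=1e-6, abs=1e-12)


class TestFoldChanges:
    @pytest.mark.parametrize(
        "fc_b,fc_p,expected", [(2, 1, 2), (0.15, 0.3, 0.5), (0.42, 0.42, 1.0)]
    )
    def test_pause_release(self, fc_b, fc_p, expected):
        assert K.fold_change_pause_release(fc_b, fc_p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fc_p,fc_b,expected",
        [(0.3, 0.15, (0.15, 0.3)), (0.25, 0.25, (0.25, 0.25)), (0.5, 1.2, (0.5, 1.2))],
    )
    def test_initiation_bounds(self, fc_p, fc_b, expected):
        assert K.fold_change_initiation_bounds(fc_p, fc_b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "r,expected",
        [(1e9, 0.3), (0.0, 0.15), (2.0, 0.25)],
    )
    def test_initiation_given_ratio(self, r, expected):
        got = K.fold_change_initiation_given_ratio(0.3, 0.5, r)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            K.fold_change_pause_release(0, 1)
        with pytest.raises(InvalidParameterError):
            K.fold_change_initiation_bounds(1, -2)

    @settings(derandomize=True, max_examples=50)
    @given(fc_p=fold, fc_krel=fold, r1=st.floats(0, 50), r2=st.floats(0, 50))
    def test_given_ratio_monotone_and_within_bounds(self, fc_p, fc_krel, r1, r2):
        fc_b = fc_krel * fc_p
        lo, up = K.fold_change_initiation_bounds(fc_p, fc_b)
        v1 = K.fold_change_initiation_given_ratio(fc_p, fc_krel, r1)
        v2 = K.fold_change_initiation_given_ratio(fc_p, fc_krel, r2)
        eps = 1e-9 * (up + 1)
        assert lo - eps <= v1 <= up + eps
        # moves monotonically from the fc_b limit (r=0) to the fc_p limit
        if r1 < r2:
            assert (v2 - v1) * (fc_p - fc_b) >= -eps


class TestAbsoluteRates:
    def test_release_from_density_ratio(self):
        assert K.pause_release_rate(2000, 50, 0.0215) == pytest.approx(0.86)

    def test_release_zero_body(self):
        assert K.pause_release_rate(1500, 10, 0) == 0

    def test_release_scale_invariance(self):
        a = K.pause_release_rate(2000, 50, 0.0215)
        b = K.pause_release_rate(2000, 50 * 8, 0.0215 * 8)
        assert a == b  # dyadic common scale: bitwise identical

    def test_release_requires_pause_signal(self):
        with pytest.raises(InvalidParameterError):
            K.pause_release_rate(2000, 0, 0.1)

    def test_initiation_inverts_steady_state(self, fig_rates):
        ss = K.steady_state(fig_rates)
        got = K.initiation_rate(ss.p, ss.b, fig_rates.k_pre, fig_rates.k_elong)
        assert got == pytest.approx(fig_rates.k_init, rel=1e-9)

    def test_initiation_no_body(self):
        assert K.initiation_rate(0.2, 0, 1.5, 2000) == pytest.approx(0.3)
        assert K.initiation_rate(0, 0, 1.5, 2000) == 0

    def test_initiation_requires_scaled(self):
        with pytest.raises(UnscaledDensityError):
            K.initiation_rate(50, 0.02, 1.5, 2000, scaled=False)

    def test_effective_release(self, fig_rates):
        assert K.effective_pause_release(1.35, 0.25) == pytest.approx(0.3375)
        assert K.effective_pause_release(2.0, 0) == 0
        ss = K.steady_state(fig_rates)
        got = K.effective_pause_release(fig_rates.k_rel, ss.p)
        assert got == pytest.approx(0.0641, rel=1e-3)

    def test_effective_release_rejects_unscaled(self):
        with pytest.raises(UnscaledDensityError):
            K.effective_pause_release(1.0, 50.0)

    def test_spacing(self, fig_rates):
        assert K.polymerase_spacing(1 / 9600) == pytest.approx(9600)
        ss = K.steady_state(fig_rates)
        assert K.polymerase_spacing(ss.b) == pytest.approx(31200, rel=1e-3)
        assert K.polymerase_spacing(0) == math.inf
        assert K.polymerase_spacing(4 * 1e-4) == K.polymerase_spacing(1e-4) / 4


class TestTerminationReleaseRatio:
    def test_worked_example(self):
        res = K.termination_release_ratio(fc_krel=0.5, fc_kinit=0.25, fc_p=0.3)
        assert res.value == pytest.approx(2.0, rel=1e-9)
        assert res.boundary is None and not res.negative

    def test_zero_boundary(self):
        # fc_kinit == fc_b == fc_krel * fc_p
        res = K.termination_release_ratio(fc_krel=0.5, fc_kinit=0.15, fc_p=0.3)
        assert res.boundary is Boundary.ZERO_BOUNDARY and res.value is None

    def test_undefined_boundary(self):
        res = K.termination_release_ratio(fc_krel=0.5, fc_kinit=0.3, fc_p=0.3)
        assert res.boundary is Boundary.UNDEFINED_BOUNDARY and res.value is None

    def test_negative_flagged_not_clipped(self):
        # fc_kinit above both bounds -> inadmissible
        res = K.termination_release_ratio(fc_krel=0.5, fc_kinit=0.45, fc_p=0.3)
        assert res.negative and res.value < 0

    @settings(derandomize=True, max_examples=200)
    @given(
        k_init=positive_rate, k_rel=positive_rate, r=st.floats(1e-3, 1e3),
        fc_kinit=fold, fc_krel=fold,
    )
    def test_round_trip_recovers_generating_ratio(
        self, k_init, k_rel, r, fc_kinit, fc_krel
    ):
        """Steady states in two conditions imply fold changes whose
        termination/release relation returns the generating k_pre/k_rel."""
        k_pre = r * k_rel
        ctl = K.steady_state(RateSet(k_init, k_pre, k_rel, 2000))
        trt = K.steady_state(
            RateSet(fc_kinit * k_init, k_pre, fc_krel * k_rel, 2000)
        )
        fc_p = trt.p / ctl.p
        fc_b = trt.b / ctl.b
        res = K.termination_release_ratio(
            K.fold_change_pause_release(fc_b, fc_p), fc_kinit, fc_p
        )
        if res.boundary is None:
            assert res.value == pytest.approx(r, rel=1e-6)


class TestHalfLife:
    def test_one_minute_total_rate(self):
        assert K.pause_half_life(math.log(2) / 2, math.log(2) / 2) == pytest.approx(60)

    def test_fast_turnover(self):
        assert K.pause_half_life(6.7 * 0.86, 0.86) == pytest.approx(6.28, abs=0.01)

    def test_representative_gene(self, fig_rates):
        got = K.pause_half_life(fig_rates.k_pre, fig_rates.k_rel)
        assert got == pytest.approx(21.3, abs=0.05)

    def test_infinite_when_no_exit(self):
        assert K.pause_half_life(0, 0) == math.inf


def test_elongation_linearity(fig_rates):
    """Doubling k_elong exactly doubles k_rel, k_pre and k_init and exactly
    halves the half-life, for fixed densities and fixed k_pre/k_rel."""
    ss = K.steady_state(fig_rates)
    r = fig_rates.k_pre / fig_rates.k_rel
    for c in (2.0, 0.5, 4.0):
        krel1 = K.pause_release_rate(fig_rates.k_elong, ss.p, ss.b)
        krel2 = K.pause_release_rate(c * fig_rates.k_elong, ss.p, ss.b)
        assert krel2 == c * krel1
        assert r * krel2 == c * (r * krel1)
        kinit1 = K.initiation_rate(ss.p, ss.b, r * krel1, fig_rates.k_elong)
        kinit2 = K.initiation_rate(ss.p, ss.b, r * krel2, c * fig_rates.k_elong)
        assert kinit2 == pytest.approx(c * kinit1, rel=1e-15)
        assert K.pause_half_life(r * krel2, krel2) == K.pause_half_life(r * krel1, krel1) / c
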