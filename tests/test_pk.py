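"""Forward one-compartment kinetics and the reverse-dosimetry inversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

import spkdose as s
from spkdose.errors import DomainError, IntervalError, NonIdentifiableError


def ode_cumulative(params, taus):
    """Independent oracle: integrate dG=-kaG, dB=kaG-keB, dU=fu*ke*B."""
    ka, ke, fu = params.k_a_eff, params.k_e, params.f_u

    def rhs(t, y):
        g, b, u = y
        return [-ka * g, ka * g - ke * b, fu * ke * b]

    sol = solve_ivp(
        rhs, (0.0, max(taus)), [1.0, 0.0, 0.0], t_eval=taus, rtol=1e-11, atol=1e-13
    )
    return sol.y[2]


class TestCumulativeExcreted:
    def test_zero_at_bolus_instant(self, params):
        assert s.cumulative_excreted(params, 0.0) == 0.0

    def test_mass_conservation_limit(self, params):
        assert s.cumulative_excreted(params, 500.0) == pytest.approx(params.f_u, abs=1e-6)

    def test_instant_absorption_reduces_to_single_exponential(self):
        p = s.PKParameters(k_a=1e6, t_half_elim=16.0)
        # with immediate absorption, half the eventual excretion by one half-life
        assert s.cumulative_excreted(p, 16.0) == pytest.approx(0.5 * p.f_u, abs=1e-4)

    def test_matches_ode_integration(self, params):
        taus = np.linspace(0.01, 96.0, 40)
        expected = ode_cumulative(params, taus)
        got = s.cumulative_excreted(params, taus)
        assert np.allclose(got, expected, rtol=1e-6, atol=1e-12)

    def test_matches_ode_for_fast_absorption(self):
        p = s.PKParameters(k_a=8.0, t_half_elim=6.0, f_u=0.35)
        taus = np.linspace(0.01, 96.0, 40)
        assert np.allclose(s.cumulative_excreted(p, taus), ode_cumulative(p, taus), rtol=1e-6)

    def test_monotone_nondecreasing_and_bounded(self, params):
        taus = np.linspace(0.0, 300.0, 500)
        m = s.cumulative_excreted(params, taus)
        assert np.all(np.diff(m) >= 0)
        assert np.all(m <= params.f_u + 1e-12)

    def test_negative_tau_rejected(self, params):
        with pytest.raises(DomainError):
            s.cumulative_excreted(params, -0.5)

    def test_ka_equal_ke_degeneracy_is_lifted(self):
        ke = math.log(2.0) / 16.0
        p = s.PKParameters(k_a=ke, t_half_elim=16.0)
        m = s.cumulative_excreted(p, np.linspace(0.0, 96.0, 50))
        assert np.all(np.isfinite(m))
        # limit form: fu * (1 - (1 + ke*tau) e^{-ke*tau})
        tau = 24.0
        expected = p.f_u * (1 - (1 + ke * tau) * math.exp(-ke * tau))
        assert s.cumulative_excreted(p, tau) == pytest.approx(expected, rel=1e-6)


class TestUnitUerAvg:
    def test_window_before_exposure_is_zero(self, params):
        assert s.unit_uer_avg(params, t0=19.0, t_p=10.0, t_c=15.0) == 0.0

    def test_equals_cumulative_increment_over_interval(self, params):
        got = s.unit_uer_avg(params, t0=19.0, t_p=21.0, t_c=31.0)
        expected = (
            s.cumulative_excreted(params, 12.0) - s.cumulative_excreted(params, 2.0)
        ) / 10.0
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_quadrature_of_instantaneous_rate(self, params):
        ka, ke, fu = params.k_a_eff, params.k_e, params.f_u
        rate = lambda t: fu * ke * ka / (ka - ke) * (
            math.exp(-ke * (t - 19.0)) - math.exp(-ka * (t - 19.0))
        )
        integral, _ = quad(rate, 21.0, 31.0)
        assert s.unit_uer_avg(params, 19.0, 21.0, 31.0) == pytest.approx(
            integral / 10.0, rel=1e-9
        )

    def test_window_straddling_exposure_ignores_pre_bolus_part(self, params):
        straddle = s.unit_uer_avg(params, t0=19.0, t_p=14.0, t_c=24.0)
        post_only = s.cumulative_excreted(params, 5.0) / 10.0
        assert straddle == pytest.approx(post_only, rel=1e-12)

    def test_shrinking_window_converges_to_instantaneous_rate(self, params):
        t = 30.0
        instantaneous = params.f_u * params.k_e * s.body_burden(params, t - 19.0)
        h = 1e-5
        fd = s.unit_uer_avg(params, 19.0, t - h, t + h)
        assert fd == pytest.approx(instantaneous, rel=1e-6)

    def test_post_peak_windows_decrease(self, params):
        t0 = 19.0
        peak = t0 + s.peak_time(params)
        starts = peak + np.arange(1.0, 30.0, 4.0)
        vals = [s.unit_uer_avg(params, t0, a, a + 3.0) for a in starts]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_degenerate_window_rejected(self, params):
        with pytest.raises(IntervalError):
            s.unit_uer_avg(params, 19.0, 21.0, 21.0)


class TestInvertDose:
    def test_zero_observation_gives_zero_dose(self, params):
        est = s.invert_dose(s.UERRecord(0.0, 21.0, 31.0), params, 19.0, 17.0)
        assert est.dose == 0.0

    def test_forward_simulated_bolus_round_trips(self, params):
        bw, dose_ug = 17.0, 100.0
        dose_umol = dose_ug / params.mw_parent
        uer = dose_umol * s.unit_uer_avg(params, 19.0, 21.0, 31.0)
        est = s.invert_dose(s.UERRecord(uer, 21.0, 31.0), params, 19.0, bw)
        assert est.dose == pytest.approx(dose_ug / bw, rel=1e-8)

    @given(st.floats(min_value=1e-6, max_value=1e3))
    def test_linear_in_observed_rate(self, uer):
        params = s.PKParameters()
        d1 = s.invert_dose(s.UERRecord(uer, 21.0, 31.0), params, 19.0, 17.0).dose
        d2 = s.invert_dose(s.UERRecord(2 * uer, 21.0, 31.0), params, 19.0, 17.0).dose
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_pre_exposure_window_not_identifiable(self, params):
        with pytest.raises(NonIdentifiableError):
            s.invert_dose(s.UERRecord(0.5, 10.0, 15.0), params, 19.0, 17.0)


class TestSimulateUerProfile:
    def test_zero_before_exposure(self, params):
        t = np.linspace(0.0, 100.0, 401)
        rate = s.simulate_uer_profile(params, 100.0, 19.0, t)
        assert np.all(rate[t < 19.0] == 0.0)

    def test_trapezoid_integral_recovers_excreted_fraction(self, params):
        t = np.linspace(19.0, 519.0, 40001)
        rate = s.simulate_uer_profile(params, 100.0, 19.0, t)
        dose_umol = 100.0 / params.mw_parent
        assert np.trapezoid(rate, t) == pytest.approx(params.f_u * dose_umol, rel=1e-3)

    def test_peak_location_matches_closed_form(self, params):
        t = np.linspace(19.0, 60.0, 200001)
        rate = s.simulate_uer_profile(params, 100.0, 19.0, t)
        assert t[np.argmax(rate)] - 19.0 == pytest.approx(s.peak_time(params), abs=1e-3)

    def test_unsorted_grid_rejected(self, params):
        with pytest.raises(DomainError):
            s.simulate_uer_profile(params, 1.0, 0.0, [0.0, 2.0, 1.0])


@given(
    t_half=st.floats(min_value=2.0, max_value=48.0),
    k_a=st.floats(min_value=0.05, max_value=10.0),
    f_u=st.floats(min_value=0.05, max_value=1.0),
)
def test_mass_conservation_for_arbitrary_parameters(t_half, k_a, f_u):
    """Cumulative excretion never exceeds f_u and approaches it monotonically."""
    p = s.PKParameters(t_half_elim=t_half, k_a=k_a, f_u=f_u)
    # the limit is governed by the slower of elimination and absorption
    horizon = 40 * max(t_half, math.log(2.0) / k_a)
    taus = np.linspace(0.0, horizon, 300)
    m = s.cumulative_excreted(p, taus)
    assert np.all(np.diff(m) >= -1e-12)
    assert np.all(m <= f_u + 1e-9)
    assert m[-1] == pytest.approx(f_u, rel=1e-4)


def test_invalid_parameters_rejected():
    for kwargs in (
        dict(t_half_elim=0.0),
        dict(k_a=-1.0),
        dict(f_u=0.0),
        dict(f_u=1.5),
    ):
        with pytest.raises(DomainError):
            s.PKParameters(**kwargs)
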