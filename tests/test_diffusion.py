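"""Fixation probability, conditional timing, and the reduced-model constants."""

import warnings

import numpy as np
import pytest

from hscniche import deduce_rates, mouse_observables
from hscniche.diffusion import (DiffusionSummary, WeakSelectionWarning,
                                b_const, b_from_observables,
                                conditional_time_moments, fixation_probability,
                                incidence_curve, lambda_const,
                                lambda_from_observables, mean_conditional_time,
                                neutral_expansion_time, required_advantage,
                                summary_from_observables)
from hscniche.parameters import DAYS_PER_YEAR, mouse_grid, round_sig


def _summary(obs, eps, dose=1.0, sigma=1.0):
    return summary_from_observables(obs, eps, dose=dose, sigma=sigma)


@pytest.mark.parametrize("obs", list(mouse_grid()),
                         ids=lambda o: f"s{o.s_star:g}_ell{o.ell_minutes:g}")
def test_dual_forms_of_drift_and_diffusion_constants(obs):
    """The rate-based and observable-based expressions for Lambda and B are
    algebraically identical."""
    params = deduce_rates(obs, epsilon=0.37)
    assert lambda_const(params) == pytest.approx(
        lambda_from_observables(obs, 0.37), rel=1e-12)
    assert b_const(params, obs.xi) == pytest.approx(
        b_from_observables(obs), rel=1e-12)


def test_constant_hand_values(mouse_fast):
    params = deduce_rates(mouse_fast, epsilon=0.1)
    assert lambda_const(params) == pytest.approx(1010.05, abs=0.01)
    assert b_const(params, mouse_fast.xi) == pytest.approx(0.025253, rel=1e-4)
    # Lambda is linear in eps, B does not depend on it
    assert lambda_const(deduce_rates(mouse_fast, epsilon=0.2)) == pytest.approx(
        2 * lambda_const(params), rel=1e-12)
    assert b_const(deduce_rates(mouse_fast, epsilon=0.9), mouse_fast.xi) == \
        pytest.approx(b_const(params, mouse_fast.xi), rel=1e-12)


def test_fixation_probability_limits_and_stability(mouse_fast):
    xi = mouse_fast.xi
    mk = lambda z0, Lam, sigma=1.0: DiffusionSummary(
        xi=xi, z0=z0, Lam=Lam, B=0.025, sigma=sigma, N=mouse_fast.N)
    assert fixation_probability(mk(0.0, 5.0)) == 0.0
    assert fixation_probability(mk(xi, 5.0)) == pytest.approx(1.0)
    # neutral limit z0/(sigma xi), checked against a vanishing Lambda
    s_neutral = mk(0.01, 0.0, sigma=0.5)
    s_small = mk(0.01, 1e-8, sigma=0.5)
    expected = 0.01 / (0.5 * xi)
    assert fixation_probability(s_neutral) == pytest.approx(expected, rel=1e-12)
    assert fixation_probability(s_small) == pytest.approx(expected, rel=1e-6)
    # no overflow/cancellation for enormous drift
    assert fixation_probability(mk(1e-6, 1e6 / xi)) == pytest.approx(
        -np.expm1(-1.0 / xi), rel=1e-9)
    # monotone in z0 and in Lambda
    phis = [fixation_probability(mk(z, 5.0)) for z in np.linspace(1e-4, xi, 20)]
    assert np.all(np.diff(phis) > 0)
    phis_eps = [fixation_probability(mk(1e-3, L)) for L in np.linspace(0, 2000, 15)]
    assert np.all(np.diff(phis_eps) >= 0)
    assert phis_eps[5] > phis_eps[0]


def test_advantaged_dose_has_even_chance(mouse_fast):
    """Eight donor cells with a 10% division advantage take over the host
    marrow more often than not."""
    s = _summary(mouse_fast, 0.1, dose=8.0, sigma=1.0)
    assert fixation_probability(s) > 0.50
    assert fixation_probability(s) == pytest.approx(0.5524, abs=2e-4)


def test_neutral_expansion_time_range():
    """A neutral clone from a single cell needs ~5 to ~45 years to reach 1%
    clonality across the murine observable range."""
    slow = _summary(mouse_observables(1.0, 5.0), 0.0, sigma=0.01)
    fast = _summary(mouse_observables(100.0, 1.0), 0.0, sigma=0.01)
    t_slow = neutral_expansion_time(slow) / DAYS_PER_YEAR
    t_fast = neutral_expansion_time(fast) / DAYS_PER_YEAR
    assert round(t_slow) == 45
    assert round_sig(t_fast, 1) == 5


def test_neutral_time_scales_linearly_in_system_size():
    from hscniche import EmpiricalObservables
    base = EmpiricalObservables(N=10_000, n_star=9_900, s_star=100.0,
                                beta=1 / 39, ell_minutes=1.0)
    double = EmpiricalObservables(N=20_000, n_star=19_800, s_star=200.0,
                                  beta=1 / 39, ell_minutes=1.0)
    t1 = neutral_expansion_time(_summary(base, 0.0, sigma=0.01))
    t2 = neutral_expansion_time(_summary(double, 0.0, dose=2.0, sigma=0.01))
    assert t2 == pytest.approx(2 * t1, rel=1e-6)


@pytest.mark.parametrize("sigma", [0.01, 0.1, 0.5, 1.0])
@pytest.mark.parametrize("dose", [1.0, 8.0])
def test_bvp_reduces_to_neutral_closed_form(mouse_fast, sigma, dose):
    """At eps = 0 the quadrature solution of the timing BVP equals the
    closed-form neutral time to 1e-6 relative."""
    s = _summary(mouse_fast, 0.0, dose=dose, sigma=sigma)
    assert mean_conditional_time(s) == pytest.approx(
        neutral_expansion_time(s), rel=1e-6)


def test_sixteen_year_takeover(mouse_fast):
    """Mean conditional takeover time for dose 8, 10% advantage: ~16 years."""
    s = _summary(mouse_fast, 0.1, dose=8.0, sigma=1.0)
    assert round(mean_conditional_time(s) / DAYS_PER_YEAR) == 16


def test_mean_time_decreasing_in_selection(mouse_fast):
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", WeakSelectionWarning)
        for eps in (0.0, 0.05, 0.1, 0.3, 0.8):
            times.append(mean_conditional_time(_summary(mouse_fast, eps, sigma=1.0)))
    assert np.all(np.diff(times) < 0)


def test_variance_nonnegative_and_vanishes_at_target(mouse_fast):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", WeakSelectionWarning)
        for eps, sigma in [(0.0, 0.01), (0.1, 1.0), (0.1, 0.04), (0.5, 0.5)]:
            T, sd = conditional_time_moments(_summary(mouse_fast, eps, sigma=sigma))
            assert T > 0 and sd >= 0
    # starting ever closer to the target: both moments collapse to zero
    xi = mouse_fast.xi
    ref_T, ref_sd = conditional_time_moments(_summary(mouse_fast, 0.1, sigma=1.0))
    moments = []
    for frac in (0.9, 0.99, 0.999, 0.9999):
        near = DiffusionSummary(xi=xi, z0=frac * 0.01 * xi, Lam=10.0, B=0.025,
                                sigma=0.01, N=mouse_fast.N)
        moments.append(conditional_time_moments(near))
    Ts, sds = zip(*moments)
    assert np.all(np.diff(Ts) < 0) and np.all(np.diff(sds) < 0)
    assert Ts[-1] < 1e-3 * ref_T and sds[-1] < 0.05 * ref_sd


def test_required_advantage_printed_values(mouse_fast):
    """Complete takeover in two years needs ~2x faster division; 1%
    clonality in two years needs only ~1.2x."""
    two_years = 2 * DAYS_PER_YEAR
    fold_total = required_advantage(two_years, 1.0, 1.0, mouse_fast)
    fold_1pct = required_advantage(two_years, 0.01, 1.0, mouse_fast)
    assert round_sig(fold_total, 1) == 2
    assert round_sig(fold_1pct, 2) == 1.2


def test_required_advantage_neutral_target(mouse_fast):
    s = _summary(mouse_fast, 0.0, sigma=0.01)
    target = neutral_expansion_time(s)
    assert required_advantage(target, 0.01, 1.0, mouse_fast) == pytest.approx(1.0, abs=1e-3)


def test_weak_selection_warning(mouse_fast):
    with pytest.warns(WeakSelectionWarning):
        mean_conditional_time(_summary(mouse_fast, 1.5, sigma=1.0))


def test_incidence_curve_shape(mouse_fast):
    s = _summary(mouse_fast, 0.1, dose=8.0, sigma=1.0)
    phi = fixation_probability(s)
    T, _ = conditional_time_moments(s)
    t = np.linspace(0.0, 4 * T, 200)
    curve = incidence_curve(s, t)
    assert np.all(np.diff(curve) >= 0)
    assert curve[-1] <= phi + 1e-12
    assert incidence_curve(s, np.array([T]))[0] == pytest.approx(phi * 0.5, rel=1e-9)


def test_summary_invariants():
    with pytest.raises(ValueError):
        DiffusionSummary(xi=0.99, z0=0.6, Lam=1.0, B=0.02, sigma=0.5, N=100)
    with pytest.raises(ValueError):
        DiffusionSummary(xi=0.99, z0=0.1, Lam=1.0, B=-0.02, sigma=1.0, N=100)
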