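"""Exact stochastic simulation: propensities, determinism, ensembles."""

import numpy as np
import pytest

from hscniche import (EmpiricalObservables, ModelParameters, deduce_rates,
                      mouse_observables)
from hscniche.gillespie import (GrowthConfig, SystemState, ensemble_hitting,
                                host_equilibrium, propensities, simulate,
                                time_to_clonality_mc)


def _prop_dict(state, params, growth=None):
    return dict(propensities(state, params, growth))


def test_propensities_full_marrow_and_absorbing(mouse_fast):
    params = deduce_rates(mouse_fast)
    N = params.N
    full = _prop_dict(SystemState(n1=N, s1=0), params)
    assert full["attachment_1"] == 0.0
    assert full["detachment_1"] == pytest.approx(params.d1 * N)
    empty = _prop_dict(SystemState(n1=0, s1=0), params)
    assert all(v == 0.0 for v in empty.values())


def test_propensities_balanced_flux_at_equilibrium():
    """At the deduced equilibrium, detachment and attachment fluxes balance
    at ~144,000 cells/day for the fast-transit corner."""
    obs = mouse_observables(s_star=100.0, ell_minutes=1.0)
    params = deduce_rates(obs)
    p = _prop_dict(SystemState(n1=9_900, s1=100), params)
    assert p["detachment_1"] == pytest.approx(144_000.0, rel=2e-3)
    assert p["attachment_1"] == pytest.approx(p["detachment_1"], rel=2e-2)


def test_seed_determinism_and_conservation():
    obs = EmpiricalObservables(N=100, n_star=99, s_star=1.0, beta=1 / 39,
                               ell_minutes=5.0)
    params = deduce_rates(obs, epsilon=0.2)
    init = SystemState(n1=90, s1=1, n2=9, s2=1)
    a = simulate(init, params, horizon=5.0, seed=123)
    b = simulate(init, params, horizon=5.0, seed=123)
    for field in ("t", "n1", "s1", "n2", "s2"):
        assert np.array_equal(getattr(a, field), getattr(b, field))
    c = simulate(init, params, horizon=5.0, seed=124)
    assert not np.array_equal(a.t, c.t)
    # hard invariants along the whole path
    assert np.all(a.n1 + a.n2 <= a.N_current)
    for field in ("n1", "s1", "n2", "s2"):
        assert np.min(getattr(a, field)) >= 0


def test_all_rates_zero_is_absorbing():
    params = ModelParameters(N=10, beta1=0, beta2=0, delta1=0, delta2=0,
                             d1=0, d2=0, a1=0, a2=0)
    traj = simulate(SystemState(n1=5, s1=2), params, horizon=10.0, seed=1)
    assert len(traj) == 1 and traj.absorbed


def test_host_equilibrium_matches_observables(reduced_obs):
    params = deduce_rates(reduced_obs)
    n_star, s_star = host_equilibrium(params)
    assert n_star == pytest.approx(reduced_obs.n_star, rel=1e-10)
    assert s_star == pytest.approx(reduced_obs.s_star, rel=1e-10)


def test_ensemble_mean_matches_ode(reduced_obs):
    """Single-species SSA ensemble mean at t = 30 days agrees with the
    deterministic integration within 3 standard errors, starting off
    equilibrium."""
    from hscniche.ode import integrate
    params = deduce_rates(reduced_obs)
    init = SystemState(n1=400, s1=20)
    grid = np.array([0.0, 30.0])
    reps = 200
    finals = np.empty((reps, 2))
    seeds = np.random.SeedSequence(4242).generate_state(reps) >> 1
    for r in range(reps):
        traj = simulate(init, params, horizon=31.0, seed=int(seeds[r]), t_grid=grid)
        finals[r] = traj.n1[-1], traj.s1[-1]
    ref = integrate(np.array([400.0, 20.0, 0.0, 0.0]), params, 30.0,
                    t_eval=np.array([0.0, 30.0]))
    for k, expected in enumerate((ref.n1[-1], ref.s1[-1])):
        mean = finals[:, k].mean()
        se = finals[:, k].std(ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < 3 * max(se, 1e-9), \
            f"component {k}: mean {mean} vs ODE {expected} (SE {se})"


def test_neutral_symmetric_split_keeps_half_chimerism():
    """With identical rates and a 50/50 marrow split, mean clonality stays
    1/2 (label symmetry)."""
    obs = EmpiricalObservables(N=60, n_star=54, s_star=2.0, beta=1 / 39,
                               ell_minutes=5.0)
    params = deduce_rates(obs)
    init = SystemState(n1=27, s1=1, n2=27, s2=1)
    grid = np.array([0.0, 100.0])
    reps = 120
    seeds = np.random.SeedSequence(7).generate_state(reps) >> 1
    final_chim = []
    for r in range(reps):
        traj = simulate(init, params, horizon=101.0, seed=int(seeds[r]), t_grid=grid)
        tot = traj.n1[-1] + traj.n2[-1]
        if tot > 0:
            final_chim.append(traj.n2[-1] / tot)
    chim = np.asarray(final_chim)
    se = chim.std(ddof=1) / np.sqrt(len(chim))
    assert abs(chim.mean() - 0.5) < 3 * se + 1e-3


def test_neutral_marrow_seeded_fixation_matches_moran():
    """Neutral fixation probability of one marrow-seeded mutant among n*
    occupied niches is ~1/n* (Moran equivalence) on a reduced system."""
    obs = EmpiricalObservables(N=50, n_star=49, s_star=1.0, beta=1 / 39,
                               ell_minutes=5.0)
    params = deduce_rates(obs)
    ens = ensemble_hitting(SystemState(n1=48, s1=1, n2=1, s2=0), params,
                           sigma=1.0, reps=2_000, seed=11)
    lo, hi = ens.ci()
    assert lo <= 1 / 49 <= hi
    assert ens.censored == 0


def test_hitting_times_nested_in_sigma():
    """On identical replicate paths (same seeds), the time to reach a lower
    clonality target is no later than to a higher one."""
    obs = EmpiricalObservables(N=50, n_star=49, s_star=1.0, beta=1 / 39,
                               ell_minutes=5.0)
    params = deduce_rates(obs, epsilon=1.0)
    init = SystemState(n1=48, s1=1, n2=1, s2=0)
    lo = ensemble_hitting(init, params, sigma=0.3, reps=300, seed=31)
    hi = ensemble_hitting(init, params, sigma=0.9, reps=300, seed=31)
    assert lo.successes >= hi.successes
    assert lo.times.mean() < hi.times.mean()


def test_time_to_clonality_warns_on_few_successes(tiny_params):
    with pytest.warns(UserWarning, match="replicates"):
        time_to_clonality_mc(1, tiny_params.with_epsilon(0.0), sigma=1.0,
                             reps=5, seed=5, host_state=(3, 0))


def test_logistic_growth_monotone_to_capacity():
    obs = EmpiricalObservables(N=20, n_star=18, s_star=1.0, beta=1 / 39,
                               ell_minutes=5.0)
    params = deduce_rates(obs)
    growth = GrowthConfig(r_per_year=3.0, K=60, N0=20)
    grid = np.linspace(0.0, 3_000.0, 40)
    traj = simulate(SystemState(n1=18, s1=1), params, horizon=3_100.0,
                    seed=8, growth=growth, t_grid=grid)
    assert np.all(np.diff(traj.N_current) >= 0)
    assert traj.N_current[0] == 20
    assert traj.N_current[-1] >= 0.9 * growth.K
    assert np.all(traj.n1 + traj.n2 <= traj.N_current)


def test_consistency_ensemble_agrees_with_diffusion(consistency_ensemble, reduced_obs):
    """Reduced-N SSA vs the one-dimensional projection: fixation within the
    binomial CI, conditional mean and SD within 3 standard errors."""
    from hscniche.diffusion import (DiffusionSummary, b_from_observables,
                                    conditional_time_moments,
                                    fixation_probability,
                                    lambda_from_observables)
    s = DiffusionSummary(xi=reduced_obs.xi, z0=1 / reduced_obs.N,
                         Lam=lambda_from_observables(reduced_obs, 0.1),
                         B=b_from_observables(reduced_obs), sigma=0.5,
                         N=reduced_obs.N)
    phi = fixation_probability(s)
    lo, hi = consistency_ensemble.ci()
    assert lo <= phi <= hi
    T, sd = conditional_time_moments(s)
    times = consistency_ensemble.times
    n = len(times)
    se_mean = times.std(ddof=1) / np.sqrt(n)
    assert abs(times.mean() - T) < 3 * se_mean
    se_sd = times.std(ddof=1) / np.sqrt(2 * (n - 1))
    assert abs(times.std(ddof=1) - sd) < 3 * se_sd
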