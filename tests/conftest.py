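import numpy as np
import pytest

from hscniche import EmpiricalObservables, deduce_rates, mouse_observables
from hscniche.gillespie import SystemState, ensemble_hitting


@pytest.fixture(scope="session")
def mouse_fast():
    """Murine observables at the fast-transit corner (s*=100, ell=3 min),
    the configuration used for the clonal-expansion worked examples."""
    return mouse_observables(s_star=100.0, ell_minutes=3.0)


@pytest.fixture(scope="session")
def mouse_slow():
    """Murine observables at the slow corner (s*=1, ell=5 min)."""
    return mouse_observables(s_star=1.0, ell_minutes=5.0)


@pytest.fixture(scope="session")
def reduced_obs():
    """Mouse-shaped observables scaled down to N=500 for stochastic
    cross-checks (n*=0.99N, s*=0.01N, ell=5 min)."""
    return EmpiricalObservables(N=500, n_star=495, s_star=5.0,
                                beta=1.0 / 39.0, ell_minutes=5.0)


@pytest.fixture(scope="session")
def tiny_obs():
    """A four-niche system small enough for exact enumeration."""
    return EmpiricalObservables(N=4, n_star=3, s_star=1.0,
                                beta=1.0 / 39.0, ell_minutes=5.0)


@pytest.fixture(scope="session")
def tiny_params(tiny_obs):
    return deduce_rates(tiny_obs)


@pytest.fixture(scope="session")
def consistency_ensemble(reduced_obs):
    """SSA ensemble at reduced N=500 with a 10% division advantage, from a
    single marrow-seeded mutant, target clonality 0.5.

    Weak selection is the analytics' stated validity regime; this ensemble
    backs the fixation-probability, mean-time and SD cross-checks.
    """
    params = deduce_rates(reduced_obs, epsilon=0.1)
    init = SystemState(n1=494, s1=5, n2=1, s2=0)
    return ensemble_hitting(init, params, sigma=0.5, reps=600, seed=777)


@pytest.fixture(scope="session")
def dose8_ensemble(reduced_obs):
    """SSA ensemble for a dose of 8 donor cells injected into the blood of
    the reduced host at equilibrium, 10% advantage, target clonality 0.5."""
    from hscniche.gillespie import fixation_probability_mc
    params = deduce_rates(reduced_obs, epsilon=0.1)
    return fixation_probability_mc(8, params, sigma=0.5, reps=400, seed=99)
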