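"""Deterministic dynamics of the two-species niche-occupancy model.

State ordering throughout is ``y = (n1, s1, n2, s2)`` — marrow and blood
counts for the host (1) and mutant/donor (2) populations.  With the
free-niche fraction ``f = (N - n1 - n2)/N`` the rate equations read

    dn_i/dt = -d_i n_i + a_i s_i f - delta'_i n_i + rho_i beta_i n_i 1[n<N]
    ds_i/dt = (d_i + (1 - rho_i 1[n<N]) beta_i) n_i - (delta_i + a_i f) s_i

reducing to the main-text system when ``delta' = rho = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import EmpiricalObservables, ModelParameters, deduce_rates


class EmptyMarrowError(ValueError):
    """Chimerism is undefined when no cell occupies the marrow."""


@dataclass(frozen=True)
class OdeSolution:
    """Continuous-state trajectory with solver diagnostics."""

    t: np.ndarray          # days
    y: np.ndarray          # shape (4, len(t)); rows n1, s1, n2, s2
    params: ModelParameters
    rtol: float
    atol: float
    nfev: int
    success: bool
    message: str = ""

    @property
    def n1(self) -> np.ndarray:
        return self.y[0]

    @property
    def s1(self) -> np.ndarray:
        return self.y[1]

    @property
    def n2(self) -> np.ndarray:
        return self.y[2]

    @property
    def s2(self) -> np.ndarray:
        return self.y[3]

    def state_at(self, at: float) -> np.ndarray:
        if not (self.t[0] <= at <= self.t[-1]):
            raise ValueError(f"time {at} outside solution range [{self.t[0]}, {self.t[-1]}]")
        out = np.empty(4)
        for k in range(4):
            out[k] = np.interp(at, self.t, self.y[k])
        return out


def rhs(t: float, y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative of ``(n1, s1, n2, s2)``.

    Satisfies the per-species balance
    ``d(n_i + s_i)/dt = beta_i n_i - delta_i s_i - delta'_i n_i``:
    migration between compartments is internal.
    """
    n1, s1, n2, s2 = y
    N = params.N
    n = n1 + n2
    free = (N - n) / N
    inside = 1.0 if n < N else 0.0
    out = np.empty(4)
    for k, i in ((0, 1), (2, 2)):
        beta, delta, dpr, d, a, rho = params.species(i)
        ni, si = y[k], y[k + 1]
        reff = rho * inside
        out[k] = -d * ni + a * si * free - dpr * ni + reff * beta * ni
        out[k + 1] = (d + (1.0 - reff) * beta) * ni - (delta + a * free) * si
    return out


def _jac(t: float, y: np.ndarray, params: ModelParameters) -> np.ndarray:
    n1, s1, n2, s2 = y
    N = params.N
    free = (N - n1 - n2) / N
    J = np.zeros((4, 4))
    for k, i in ((0, 1), (2, 2)):
        beta, delta, dpr, d, a, rho = params.species(i)
        ni, si = y[k], y[k + 1]
        # d(dn_i)/d(n1), d(n2): the free fraction couples the species
        for kk in (0, 2):
            J[k, kk] += -a * si / N
            J[k + 1, kk] += a * si / N
        J[k, k] += -d - dpr + rho * beta
        J[k, k + 1] += a * free
        J[k + 1, k] += d + (1.0 - rho) * beta
        J[k + 1, k + 1] += -(delta + a * free)
    return J


def integrate(initial, params: ModelParameters, horizon: float,
              rtol: float = 1e-9, atol: float = 1e-9,
              t_eval=None, method: str = "LSODA") -> OdeSolution:
    """Integrate the rate equations over ``[0, horizon]`` days.

    The system is stiff for realistic parameters (rates span roughly
    1e-3 to 1e5 per day), so a stiff-capable solver with the analytic
    Jacobian is used by default.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (4,):
        raise ValueError("initial state must be (n1, s1, n2, s2)")
    sol = solve_ivp(rhs, (0.0, horizon), y0, args=(params,), method=method,
                    jac=_jac, rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message} (nfev={sol.nfev})")
    return OdeSolution(t=sol.t, y=sol.y, params=params, rtol=rtol, atol=atol,
                       nfev=sol.nfev, success=sol.success, message=sol.message)


def single_species_equilibrium(obs: EmpiricalObservables) -> np.ndarray:
    """Host-only equilibrium state ``(n*, s*, 0, 0)``."""
    return np.array([obs.n_star, obs.s_star, 0.0, 0.0])


def attachment_fraction(obs: EmpiricalObservables) -> tuple[float, float]:
    """Probability that a blood cell attaches before dying, near the host
    equilibrium, in two algebraically equivalent forms.

    Form 1 balances the attachment and death hazards,
    ``r/(delta + r)`` with ``r = a (N - n*)/N``; form 2 is the
    observable-only simplification ``1 - beta * ell * n*/s*``.  The two
    agree exactly because ``a (N - n*)/N + delta = 1/ell``.
    """
    params = deduce_rates(obs)
    r = params.a1 * (obs.N - obs.n_star) / obs.N
    form1 = r / (params.delta1 + r)
    form2 = 1.0 - obs.beta * obs.ell_days * obs.n_star / obs.s_star
    return form1, form2


def small_dose_attachment(dose: float, obs: EmpiricalObservables) -> float:
    """Expected number of injected donor cells that settle in the marrow.

    Valid in the small-dose regime ``dose << N - n*`` where the free-niche
    fraction is unchanged by the dose; each injected cell independently
    attaches with probability ``1 - beta * ell * n*/s*``.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if dose > 0.1 * (obs.N - obs.n_star):
        warnings.warn(
            f"dose {dose} is not small against the {obs.N - obs.n_star:.0f} free niches; "
            "the small-dose attachment formula under-counts saturation",
            stacklevel=2)
    form1, form2 = attachment_fraction(obs)
    return form2 * dose


def chimerism(solution: OdeSolution, at: float, compartment: str = "bm") -> float:
    """Fraction of marrow (default) or blood cells descending from the
    mutant/donor population at time ``at``."""
    n1, s1, n2, s2 = solution.state_at(at)
    if compartment == "bm":
        tot = n1 + n2
        part = n2
    elif compartment == "blood":
        tot = s1 + s2
        part = s2
    else:
        raise ValueError("compartment must be 'bm' or 'blood'")
    if tot <= 0:
        raise EmptyMarrowError(f"no cells in compartment '{compartment}' at t={at}")
    return part / tot


def initial_phase_end(solution: OdeSolution, obs: EmpiricalObservables,
                      blood_tol: float = 0.01, slope_tol: float = 1e-6) -> float:
    """First time at which the transplant's initial dynamical phase is over.

    Defined as the earliest grid time where the total blood pool is within
    ``blood_tol`` (relative) of its equilibrium and the donor marrow count
    changes slower than ``slope_tol * n*`` per day.  Falls back to the
    final time if the plateau is not reached within the solution horizon.
    """
    s_tot = solution.s1 + solution.s2
    dn2 = np.gradient(solution.n2, solution.t)
    ok = (np.abs(s_tot - obs.s_star) <= blood_tol * obs.s_star) & \
         (np.abs(dn2) < slope_tol * obs.n_star)
    idx = np.nonzero(ok)[0]
    return float(solution.t[idx[0]]) if idx.size else float(solution.t[-1])
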