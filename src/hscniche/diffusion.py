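"""Fast-variable-elimination analytics for clonal expansion.

Projecting the four-dimensional stochastic system onto the slow direction
yields a one-dimensional diffusion for the scaled mutant marrow count
``z = n2/N`` on ``[0, xi]``, ``xi = n*/N``.  Two constants summarise the
reduced model:

    Lambda = eps * N * (d b + d delta + b delta) / ((d + b) delta)
           = eps * N * (1 + s*/n* - b ell)                (drift/diffusion)
    B      = d (d + b) b delta^2 / (xi (d b + d delta + b delta)^2)
           = (b N / s*) * (s*/n* - b ell) / (1 + s*/n* - b ell)^2   [per day]

with ``b = beta``.  The probability that a clone starting at ``z0``
reaches a fraction ``sigma`` of the occupied niches is the standard
biased-Brownian hitting probability

    phi(z0, sigma) = (1 - exp(-Lambda z0)) / (1 - exp(-Lambda sigma xi))

and the mean conditional time T = theta/phi solves the backward boundary
value problem

    theta'' + Lambda theta' = -(N/B) phi(z)/(z (xi - z)),
    theta(0) = theta(sigma xi) = 0,

solved here in closed integral form by variation of parameters.  The
derivation assumes weak selection (0 <= eps << 1); calling the timing
functions with eps >= 1 emits a warning but still evaluates the formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from .ode import small_dose_attachment
from .parameters import EmpiricalObservables, ModelParameters, deduce_rates

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-10, limit=500)


class WeakSelectionWarning(UserWarning):
    """The projection is derived for 0 <= eps << 1."""


@dataclass(frozen=True)
class DiffusionSummary:
    """Reduced-model constants feeding the fixation/timing formulas.

    Attributes
    ----------
    xi : float
        Equilibrium occupied-niche fraction ``n*/N``.
    z0 : float
        Initial mutant marrow fraction ``n2/N`` (continuous; for a dose
        injected into the blood use the expected attachment count).
    Lam : float
        Drift-to-diffusion constant; proportional to the selection
        coefficient ``eps``.
    B : float
        Diffusion magnitude, per day.
    sigma : float
        Target clonality fraction in (0, 1].
    N : int
        Niche count (sets the timescale ``N/B``).
    """

    xi: float
    z0: float
    Lam: float
    B: float
    sigma: float
    N: int

    def __post_init__(self) -> None:
        if not 0 < self.xi < 1:
            raise ValueError(f"xi must lie in (0, 1), got {self.xi}")
        if not 0 < self.sigma <= 1:
            raise ValueError(f"sigma must lie in (0, 1], got {self.sigma}")
        if not 0 <= self.z0 <= self.sigma * self.xi:
            raise ValueError(
                f"z0 must lie in [0, sigma*xi] = [0, {self.sigma * self.xi:.6g}], got {self.z0}")
        if self.B <= 0:
            raise ValueError(f"B must be positive, got {self.B}")


def lambda_const(params: ModelParameters) -> float:
    """Drift constant Lambda from the model rates (species-1 rates and the
    selection coefficient carried by the parameter set)."""
    b, delta, d = params.beta1, params.delta1, params.d1
    eps = params.epsilon
    return eps * params.N * (d * b + d * delta + b * delta) / ((d + b) * delta)


def lambda_from_observables(obs: EmpiricalObservables, epsilon: float) -> float:
    """Equivalent observable-only form: ``eps N (1 + s*/n* - beta ell)``."""
    return epsilon * obs.N * (1.0 + obs.s_star / obs.n_star - obs.beta * obs.ell_days)


def b_const(params: ModelParameters, xi: float) -> float:
    """Diffusion constant B (per day) from the model rates.

    Selection does not enter B; it is evaluated from the species-1 rates.
    """
    b, delta, d = params.beta1, params.delta1, params.d1
    denom = d * b + d * delta + b * delta
    return d * (d + b) * b * delta ** 2 / (xi * denom ** 2)


def b_from_observables(obs: EmpiricalObservables) -> float:
    """Equivalent observable-only form of B."""
    q = obs.s_star / obs.n_star - obs.beta * obs.ell_days
    if q <= 0:
        from .parameters import InvalidRegimeError
        raise InvalidRegimeError("s*/n* must exceed beta*ell (equivalently d > 0)")
    return (obs.beta * obs.N / obs.s_star) * q / (1.0 + q) ** 2


def summary_from_observables(obs: EmpiricalObservables, epsilon: float,
                             dose: float = 1.0, sigma: float = 1.0) -> DiffusionSummary:
    """Build the reduced-model summary for a dose of cells injected into
    the blood of a host at equilibrium.

    ``z0`` is the expected number of dose cells that settle in the marrow
    (continuous, not rounded) divided by ``N``.
    """
    deduce_rates(obs)  # validate regime
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # dose-size warning not relevant for z0
        n2 = small_dose_attachment(dose, obs)
    return DiffusionSummary(xi=obs.xi, z0=n2 / obs.N,
                            Lam=lambda_from_observables(obs, epsilon),
                            B=b_from_observables(obs), sigma=sigma, N=obs.N)


def _g(w: float, Lam: float) -> float:
    """Antiderivative kernel g(w) = (1 - exp(-Lam w))/Lam, -> w as Lam -> 0."""
    if Lam == 0.0:
        return w
    return -np.expm1(-Lam * w) / Lam


def fixation_probability(summary: DiffusionSummary) -> float:
    """Probability that the clone reaches clonality ``sigma`` before dying out.

    Computed as ``g(z0)/g(sigma xi)`` with the cancellation-free kernel,
    stable for |Lambda sigma xi| up to ~1e6 and exact in the neutral
    limit (``z0 / (sigma xi)``).
    """
    L = summary.sigma * summary.xi
    if summary.z0 == 0.0:
        return 0.0
    phi = _g(summary.z0, summary.Lam) / _g(L, summary.Lam)
    return min(phi, 1.0)


def neutral_expansion_time(summary: DiffusionSummary) -> float:
    """Closed-form mean conditional expansion time (days) for a neutral clone:

        T = (N/B) [ ((xi - z0)/z0) ln(xi/(xi - z0)) + ((1-sigma)/sigma) ln(1-sigma) ]

    The ``sigma = 1`` limit of the second bracket term is 0.
    """
    xi, z0, sigma = summary.xi, summary.z0, summary.sigma
    if not 0 < z0 < sigma * xi or not z0 < xi:
        raise ValueError(f"require 0 < z0 < sigma*xi, got z0={z0}, sigma*xi={sigma * xi}")
    first = -((xi - z0) / z0) * np.log1p(-z0 / xi)
    second = 0.0 if sigma == 1.0 else ((1.0 - sigma) / sigma) * np.log1p(-sigma)
    T = (summary.N / summary.B) * (first + second)
    if T <= 0:
        raise ValueError("non-positive neutral time; invalid summary")
    return T


def _check_weak_selection(Lam: float, N: int) -> None:
    eps = Lam and abs(Lam) / N  # rough eps scale at xi ~ 1
    if eps and eps >= 0.9:
        warnings.warn(
            "timing analytics are derived under weak selection (eps << 1); "
            f"effective eps ~ {eps:.2g} is outside that regime",
            WeakSelectionWarning, stacklevel=3)


def _theta_integrals(summary: DiffusionSummary):
    """Return callables (w, gL, points) used by the BVP integral solution.

    ``w(u, L)`` is the smooth integrand f(u) g(L-u) with
    f(u) = (N/B) phi(u)/(u (xi-u)).  The apparent endpoint singularities
    cancel: phi(u)/u is finite at 0, and for sigma = 1 the factor
    g(xi - u) cancels the 1/(xi - u) pole.
    """
    xi, Lam, sigma = summary.xi, summary.Lam, summary.sigma
    NB = summary.N / summary.B
    L = sigma * xi
    gL = _g(L, Lam)

    def w(u: float, Lup: float) -> float:
        if u <= 0.0:
            return NB * _g(Lup, Lam) / (gL * xi)
        gu_over_u = 1.0 if Lam == 0.0 else -np.expm1(-Lam * u) / (Lam * u)
        return NB * gu_over_u * _g(Lup - u, Lam) / (gL * (xi - u))

    pts = []
    if Lam != 0.0:
        scale = 1.0 / abs(Lam)
        for p in (scale, 10 * scale, L - scale, L - 10 * scale):
            if 0.0 < p < L:
                pts.append(p)
    return w, gL, sorted(set(pts))


def mean_conditional_time(summary: DiffusionSummary) -> float:
    """Mean time (days) to reach clonality ``sigma``, conditioned on reaching it.

    Variation of parameters on the backward BVP gives

        T(z0) = I(sigma xi) - I_partial(z0) / phi(z0),
        I(L') = integral_0^{L'} f(u) g(L' - u) du,

    evaluated by adaptive quadrature (relative tolerance 1e-10, with
    breakpoints at the 1/Lambda boundary layers for strong drift).
    At eps = 0 this reproduces the neutral closed form to ~1e-10.
    """
    xi, z0, sigma, Lam = summary.xi, summary.z0, summary.sigma, summary.Lam
    if not 0 < z0 < sigma * xi:
        raise ValueError(f"require 0 < z0 < sigma*xi, got z0={z0}")
    _check_weak_selection(Lam, summary.N)
    w, gL, pts = _theta_integrals(summary)
    L = sigma * xi
    I_full, err_full = quad(lambda u: w(u, L), 0.0, L, points=pts or None, **_QUAD_OPTS)
    phi = fixation_probability(summary)
    pts2 = [p for p in pts if p < z0]
    I_part, err_part = quad(lambda u: w(u, z0), 0.0, z0, points=pts2 or None, **_QUAD_OPTS)
    T = I_full - I_part / phi
    if not np.isfinite(T) or T <= 0:
        raise RuntimeError(
            f"quadrature failed for mean conditional time: T={T}, "
            f"abserr=({err_full:.2g}, {err_part:.2g})")
    return T


def _gauss_legendre_cache(order: int = 120):
    nodes, weights = np.polynomial.legendre.leggauss(order)
    return nodes, weights


_GL_NODES, _GL_WEIGHTS = _gauss_legendre_cache()


def _theta(z: float, summary: DiffusionSummary, w, gL, I_full: float) -> float:
    """theta(z) = phi(z) I(sigma xi) - I_partial(z), via fixed-order
    Gauss-Legendre on [0, z] (integrand smooth)."""
    if z <= 0.0:
        return 0.0
    u = 0.5 * z * (_GL_NODES + 1.0)
    vals = np.array([w(ui, z) for ui in u])
    I_part = 0.5 * z * float(_GL_WEIGHTS @ vals)
    phi_z = _g(z, summary.Lam) / gL
    return phi_z * I_full - I_part


def conditional_time_moments(summary: DiffusionSummary) -> tuple[float, float]:
    """(mean, standard deviation) in days of the conditional time to
    clonality ``sigma``.

    The second moment solves the same backward operator with source
    ``-2 (N/B) theta(z)/(z (xi - z))``; the variance is
    ``theta2/phi - T^2`` and must be non-negative.
    """
    xi, z0, sigma, Lam = summary.xi, summary.z0, summary.sigma, summary.Lam
    if not 0 < z0 < sigma * xi:
        raise ValueError(f"require 0 < z0 < sigma*xi, got z0={z0}")
    _check_weak_selection(Lam, summary.N)
    w, gL, pts = _theta_integrals(summary)
    L = sigma * xi
    NB = summary.N / summary.B
    I_full = quad(lambda u: w(u, L), 0.0, L, points=pts or None, **_QUAD_OPTS)[0]
    phi = fixation_probability(summary)
    I_part = quad(lambda u: w(u, z0), 0.0, z0,
                  points=[p for p in pts if p < z0] or None, **_QUAD_OPTS)[0]
    T = I_full - I_part / phi

    def h_times_g(u: float, Lup: float) -> float:
        # 2 (N/B) theta(u)/(u (xi-u)) * g(Lup - u); endpoint limits are finite/zero
        if u >= Lup:
            return 0.0
        if u <= 0.0:
            # theta(u)/u -> finite slope at the origin
            du = 1e-9 * L
            slope = _theta(du, summary, w, gL, I_full) / du
            return 2.0 * NB * slope * _g(Lup, summary.Lam) / xi
        th = _theta(u, summary, w, gL, I_full)
        return 2.0 * NB * th / (u * (xi - u)) * _g(Lup - u, summary.Lam)

    opts = dict(epsabs=1e-10, epsrel=1e-8, limit=300)
    J_full = quad(lambda u: h_times_g(u, L), 0.0, L, points=pts or None, **opts)[0]
    J_part = quad(lambda u: h_times_g(u, z0), 0.0, z0,
                  points=[p for p in pts if p < z0] or None, **opts)[0]
    theta2 = phi * J_full - J_part
    t2 = theta2 / phi
    var = t2 - T * T
    if var < 0:
        if var > -1e-6 * t2:  # numerical epsilon around a genuinely tiny variance
            var = 0.0
        else:
            raise RuntimeError(
                f"negative variance from second-moment BVP: var={var:.4g}, "
                f"T={T:.6g}, t2={t2:.6g} (quadrature diagnostics above tolerance)")
    return T, float(np.sqrt(var))


def time_std(summary: DiffusionSummary) -> float:
    """Standard deviation (days) of the conditional time to clonality."""
    return conditional_time_moments(summary)[1]


def required_advantage(target_time_days: float, sigma: float, dose: float,
                       obs: EmpiricalObservables,
                       eps_bracket: tuple[float, float] = (1e-6, 30.0)) -> float:
    """Fold reproductive advantage ``beta2/beta`` needed for the mean
    conditional time to clonality ``sigma`` to equal ``target_time_days``.

    Root-finds the selection coefficient (mean time is decreasing in
    ``eps``); returns ``1 + eps``.
    """
    def objective(eps: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", WeakSelectionWarning)
            s = summary_from_observables(obs, eps, dose=dose, sigma=sigma)
            return mean_conditional_time(s) - target_time_days

    lo, hi = eps_bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo < 0:  # already faster than target at ~neutral
        return 1.0
    if f_hi > 0:
        raise ValueError(
            f"target time {target_time_days} d not reachable for eps <= {hi}; "
            f"residual at bracket end: {f_hi:.4g} d")
    eps = brentq(objective, lo, hi, xtol=1e-10, rtol=1e-12)
    return 1.0 + eps


def incidence_curve(summary: DiffusionSummary, t_days: np.ndarray) -> np.ndarray:
    """Cumulative probability that the clone has reached clonality ``sigma``
    by each time in ``t_days``.

    Gaussian approximation: conditional times are taken normal with the
    computed mean and SD, and the curve is scaled by the fixation
    probability, so it saturates at ``phi``.
    """
    T, sd = conditional_time_moments(summary)
    phi = fixation_probability(summary)
    t = np.asarray(t_days, dtype=float)
    if sd == 0:
        return phi * (t >= T).astype(float)
    return phi * norm.cdf(t, loc=T, scale=sd)
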