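"""Observable and rate parameter types for the niche-occupancy model.

The model has two compartments: a bone marrow (BM) with ``N`` niches, each
holding at most one hematopoietic stem cell (HSC), and an unbounded
peripheral blood (PB) pool.  Cells divide in the marrow at rate ``beta``
(daughter ejected into the blood), die in the blood at rate ``delta``,
detach from niches at rate ``d`` and re-attach from the blood at rate
``a * (N - n) / N`` per cell.

The three unmeasured rates (``delta``, ``d``, ``a``) are fully determined
by five steady-state observables — total niches ``N``, occupied niches
``n*``, blood pool size ``s*``, division rate ``beta`` and blood residence
time ``ell`` — via the deterministic steady state:

    delta = beta * n* / s*
    d     = s* / (ell * n*) - beta
    a     = (1/ell - beta * n* / s*) * N / (N - n*)

with ``ell`` in days.  All rates in this package are per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

MINUTES_PER_DAY = 1440.0
DAYS_PER_YEAR = 365.0
DAYS_PER_WEEK = 7.0

#: Murine steady-state observables reported in the experimental literature.
MOUSE_N = 10_000
MOUSE_N_STAR = 9_900
MOUSE_BETA = 1.0 / 39.0  # per day
MOUSE_S_STAR_GRID = (1.0, 10.0, 100.0)
MOUSE_ELL_GRID = (1.0, 5.0)  # minutes


class InvalidRegimeError(ValueError):
    """Observables imply a non-positive rate; the model cannot hold."""


@dataclass(frozen=True)
class EmpiricalObservables:
    """Measurable steady-state quantities that pin down the model rates.

    Parameters
    ----------
    N : int
        Total number of bone-marrow niches.
    n_star : float
        Occupied niches at equilibrium (0 < n_star < N).
    s_star : float
        Peripheral-blood HSC pool at equilibrium.  May be non-integer:
        the observable is a time average.
    beta : float
        Symmetric division rate, per day.
    ell_minutes : float
        Mean residence time of an HSC in the blood, minutes.
    """

    N: int
    n_star: float
    s_star: float
    beta: float
    ell_minutes: float

    def __post_init__(self) -> None:
        if not (0 < self.n_star < self.N):
            raise ValueError(f"require 0 < n_star < N, got n_star={self.n_star}, N={self.N}")
        if self.s_star <= 0:
            raise ValueError(f"s_star must be positive, got {self.s_star}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.ell_minutes <= 0:
            raise ValueError(f"ell_minutes must be positive, got {self.ell_minutes}")

    @property
    def ell_days(self) -> float:
        return self.ell_minutes / MINUTES_PER_DAY

    @property
    def xi(self) -> float:
        """Equilibrium occupied-niche fraction n*/N."""
        return self.n_star / self.N


class BloodFlux(NamedTuple):
    """Daily marrow→blood cell flux and mean niche residency."""

    flux_per_day: float
    bm_residency_days: float


@dataclass(frozen=True)
class ModelParameters:
    """Per-species rate constants of the two-species reaction system.

    Species 1 is the host/wildtype population, species 2 the mutant or
    donor clone.  The main-text configuration has no in-niche death
    (``delta_niche = 0``), daughters always ejected into the blood
    (``rho = 0``) and all rates except ``beta`` equal across species,
    with ``beta2 = (1 + epsilon) * beta1``.
    """

    N: int
    beta1: float
    beta2: float
    delta1: float
    delta2: float
    d1: float
    d2: float
    a1: float
    a2: float
    delta_niche1: float = 0.0
    delta_niche2: float = 0.0
    rho1: float = 0.0
    rho2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "delta1", "delta2", "d1", "d2",
                     "a1", "a2", "delta_niche1", "delta_niche2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("rho1", "rho2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {getattr(self, name)}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")

    @property
    def epsilon(self) -> float:
        """Selection coefficient: beta2 = (1 + epsilon) * beta1."""
        return self.beta2 / self.beta1 - 1.0

    def with_epsilon(self, epsilon: float) -> "ModelParameters":
        return replace(self, beta2=(1.0 + epsilon) * self.beta1)

    def species(self, i: int) -> tuple[float, float, float, float, float, float]:
        """(beta, delta, delta_niche, d, a, rho) for species ``i`` in {1, 2}."""
        if i not in (1, 2):
            raise ValueError("species index must be 1 or 2")
        g = lambda stem: getattr(self, f"{stem}{i}")
        return (g("beta"), g("delta"), g("delta_niche"), g("d"), g("a"), g("rho"))


def deduce_rates(obs: EmpiricalObservables, epsilon: float = 0.0,
                 alpha: float = 0.0, rho: float = 0.0) -> ModelParameters:
    """Deduce (delta, d, a) from steady-state observables.

    The single-species deterministic steady state at ``(n*, s*)`` inverts to

        delta = beta * n* / s*
        d     = s* / (ell * n*) - beta
        a     = (1/ell - beta * n* / s*) * N / (N - n*)

    Parameters
    ----------
    obs : EmpiricalObservables
    epsilon : float
        Selection coefficient of species 2 (``beta2 = (1+epsilon)*beta``).
    alpha : float
        In-niche death as a fraction of blood death: ``delta' = alpha*delta``.
    rho : float
        Probability a daughter cell attaches directly to a free niche.

    Raises
    ------
    InvalidRegimeError
        If the observables imply ``d <= 0`` or ``a <= 0`` (e.g. blood
        turnover slower than the division rate can sustain).
    """
    ell = obs.ell_days
    delta = obs.beta * obs.n_star / obs.s_star
    d = obs.s_star / (ell * obs.n_star) - obs.beta
    a = (1.0 / ell - delta) * obs.N / (obs.N - obs.n_star)
    if d <= 0:
        raise InvalidRegimeError(
            f"detachment rate d = s*/(ell*n*) - beta = {d:.4g} per day is <= 0; "
            "blood turnover s*/(ell*n*) must exceed beta")
    if a <= 0:
        raise InvalidRegimeError(
            f"attachment rate a = {a:.4g} per day is <= 0; "
            "1/ell must exceed beta*n*/s*")
    return ModelParameters(
        N=obs.N,
        beta1=obs.beta, beta2=(1.0 + epsilon) * obs.beta,
        delta1=delta, delta2=delta,
        d1=d, d2=d,
        a1=a, a2=a,
        delta_niche1=alpha * delta, delta_niche2=alpha * delta,
        rho1=rho, rho2=rho,
    )


def blood_flux(obs: EmpiricalObservables) -> BloodFlux:
    """Daily flux of cells leaving the marrow (= ``s*/ell``) and the mean
    time a cell stays attached to a niche (= ``1/d``)."""
    params = deduce_rates(obs)
    return BloodFlux(flux_per_day=obs.s_star / obs.ell_days,
                     bm_residency_days=1.0 / params.d1)


def mouse_observables(s_star: float = 100.0, ell_minutes: float = 1.0) -> EmpiricalObservables:
    """Murine observables: N = 10^4 niches, n* = 9,900 occupied, beta = 1/39
    per day; ``s*`` (1–100 cells) and ``ell`` (1–5 minutes) span the ranges
    reported in the literature."""
    return EmpiricalObservables(N=MOUSE_N, n_star=MOUSE_N_STAR, s_star=s_star,
                                beta=MOUSE_BETA, ell_minutes=ell_minutes)


def mouse_grid() -> Iterator[EmpiricalObservables]:
    """All six (s*, ell) combinations of the murine observable ranges."""
    for s_star in MOUSE_S_STAR_GRID:
        for ell in MOUSE_ELL_GRID:
            yield mouse_observables(s_star=s_star, ell_minutes=ell)


def human_observables(N: int, beta_per_week: float = 1.0 / 40.0,
                      ell_minutes: float = 60.0, s_frac: float = 0.01,
                      occ_frac: float = 0.99) -> EmpiricalObservables:
    """Human-scale observables extrapolated from the murine values.

    Defaults: division once per 40 weeks, one hour in the blood,
    ``s* = 0.01 N`` and ``n* = 0.99 N`` — a tenfold slow-down of the
    mouse timescales, matching the scaling of the division rate.
    """
    if N < 100:
        raise ValueError(f"N must be >= 100 for the scaling rules, got {N}")
    return EmpiricalObservables(N=N, n_star=occ_frac * N, s_star=s_frac * N,
                                beta=beta_per_week / DAYS_PER_WEEK,
                                ell_minutes=ell_minutes)


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (for comparisons against
    printed tables)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
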