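"""Exact stochastic simulation (direct-method SSA) of the two-species
niche-occupancy reaction system.

Reactions, per species i (rates per day):

    reproduction   beta_i n_i     daughter to a free niche w.p. rho_i (if n < N),
                                  otherwise ejected into the blood
    blood death    delta_i s_i
    niche death    delta'_i n_i
    detachment     d_i n_i        niche -> blood
    attachment     a_i s_i (N-n)/N   blood -> niche

plus an optional logistic niche-addition event with propensity
``r N (1 - N/K)`` modelling a maturing marrow.

The hot loops are compiled with numba when available; a pure-Python
fallback keeps the module importable (but slow) without it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import beta as _beta_dist

from .parameters import ModelParameters

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class GrowthConfig:
    """Logistic niche-pool growth: one niche added at propensity
    ``r N (1 - N/K)``, with ``r`` given per year."""

    r_per_year: float
    K: int
    N0: int

    def __post_init__(self) -> None:
        if not 0 < self.N0 <= self.K:
            raise ValueError(f"require 0 < N0 <= K, got N0={self.N0}, K={self.K}")
        if self.r_per_year < 0:
            raise ValueError(f"r must be >= 0, got {self.r_per_year}")

    @property
    def r_per_day(self) -> float:
        return self.r_per_year / 365.0


@dataclass(frozen=True)
class SystemState:
    """Counts of each sub-population: marrow (n) and blood (s) per species."""

    n1: int
    s1: int
    n2: int = 0
    s2: int = 0
    t: float = 0.0
    N_current: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n1, self.s1, self.n2, self.s2) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Recorded states over time plus reproducibility metadata."""

    t: np.ndarray
    n1: np.ndarray
    s1: np.ndarray
    n2: np.ndarray
    s2: np.ndarray
    N_current: np.ndarray
    seed: int
    params: ModelParameters
    absorbed: bool = False

    def __len__(self) -> int:
        return self.t.shape[0]

    def clonality(self) -> np.ndarray:
        tot = self.n1 + self.n2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n2 / np.maximum(tot, 1), np.nan)


def propensities(state: SystemState, params: ModelParameters,
                 growth: Optional[GrowthConfig] = None) -> list[tuple[str, float]]:
    """Per-event propensities at ``state`` (inspection/reference path;
    the simulation kernels compute the same quantities inline)."""
    N = state.N_current if state.N_current is not None else params.N
    n = state.n1 + state.n2
    if n > N:
        raise ValueError(f"occupied niches {n} exceed niche count {N}")
    free = (N - n) / N
    out = []
    for i, (ni, si) in ((1, (state.n1, state.s1)), (2, (state.n2, state.s2))):
        b, de, dpr, d, a, rho = params.species(i)
        out += [
            (f"reproduction_{i}", b * ni),
            (f"blood_death_{i}", de * si),
            (f"niche_death_{i}", dpr * ni),
            (f"detachment_{i}", d * ni),
            (f"attachment_{i}", a * si * free),
        ]
    if growth is not None and growth.r_per_year > 0:
        out.append(("niche_growth", growth.r_per_day * N * (1.0 - N / growth.K)))
    return out


# --- compiled kernels -------------------------------------------------------
# State update shared by all kernels.  Event indices:
# 0/1 reproduction, 2/3 blood death, 4/5 niche death, 6/7 detachment,
# 8/9 attachment (even = species 1), 10 niche growth.

@njit(cache=True)
def _draw_event(n1, s1, n2, s2, Ncur, K, rg, b1, b2, de1, de2, dp1, dp2,
                d1, d2, a1, a2):
    free = (Ncur - n1 - n2) / Ncur
    p0 = b1 * n1
    p1 = b2 * n2
    p2 = de1 * s1
    p3 = de2 * s2
    p4 = dp1 * n1
    p5 = dp2 * n2
    p6 = d1 * n1
    p7 = d2 * n2
    p8 = a1 * s1 * free
    p9 = a2 * s2 * free
    p10 = 0.0
    if rg > 0.0 and Ncur < K:
        p10 = rg * Ncur * (1.0 - Ncur / K)
    total = p0 + p1 + p2 + p3 + p4 + p5 + p6 + p7 + p8 + p9 + p10
    if total <= 0.0:
        return -1, 0.0
    r = np.random.random() * total
    if r < p0:
        return 0, total
    r -= p0
    if r < p1:
        return 1, total
    r -= p1
    if r < p2:
        return 2, total
    r -= p2
    if r < p3:
        return 3, total
    r -= p3
    if r < p4:
        return 4, total
    r -= p4
    if r < p5:
        return 5, total
    r -= p5
    if r < p6:
        return 6, total
    r -= p6
    if r < p7:
        return 7, total
    r -= p7
    if r < p8:
        return 8, total
    r -= p8
    if r < p9:
        return 9, total
    return 10, total


@njit(cache=True)
def _apply(ev, n1, s1, n2, s2, Ncur, rho1, rho2):
    if ev == 0:
        if rho1 > 0.0 and n1 + n2 < Ncur and np.random.random() < rho1:
            n1 += 1
        else:
            s1 += 1
    elif ev == 1:
        if rho2 > 0.0 and n1 + n2 < Ncur and np.random.random() < rho2:
            n2 += 1
        else:
            s2 += 1
    elif ev == 2:
        s1 -= 1
    elif ev == 3:
        s2 -= 1
    elif ev == 4:
        n1 -= 1
    elif ev == 5:
        n2 -= 1
    elif ev == 6:
        n1 -= 1
        s1 += 1
    elif ev == 7:
        n2 -= 1
        s2 += 1
    elif ev == 8:
        n1 += 1
        s1 -= 1
    elif ev == 9:
        n2 += 1
        s2 -= 1
    else:
        Ncur += 1
    return n1, s1, n2, s2, Ncur


@njit(cache=True)
def _ssa_grid(n1, s1, n2, s2, Ncur, K, rg, b1, b2, de1, de2, dp1, dp2,
              d1, d2, a1, a2, rho1, rho2, t_grid, out, seed):
    """Record the state on a fixed time grid; returns (absorbed, final t)."""
    np.random.seed(seed)
    t = 0.0
    gi = 0
    ng = t_grid.shape[0]
    while gi < ng:
        ev, total = _draw_event(n1, s1, n2, s2, Ncur, K, rg, b1, b2, de1, de2,
                                dp1, dp2, d1, d2, a1, a2)
        if ev < 0:
            while gi < ng:
                out[gi, 0] = n1
                out[gi, 1] = s1
                out[gi, 2] = n2
                out[gi, 3] = s2
                out[gi, 4] = Ncur
                gi += 1
            return True, t
        t_new = t - math.log(np.random.random()) / total
        while gi < ng and t_grid[gi] < t_new:
            out[gi, 0] = n1
            out[gi, 1] = s1
            out[gi, 2] = n2
            out[gi, 3] = s2
            out[gi, 4] = Ncur
            gi += 1
        n1, s1, n2, s2, Ncur = _apply(ev, n1, s1, n2, s2, Ncur, rho1, rho2)
        t = t_new
    return False, t


@njit(cache=True)
def _ssa_events(n1, s1, n2, s2, Ncur, K, rg, b1, b2, de1, de2, dp1, dp2,
                d1, d2, a1, a2, rho1, rho2, t_max, out_t, out_s, seed):
    """Record every event time up to ``t_max`` or the record capacity.

    Returns (n_records, absorbed, truncated).
    """
    np.random.seed(seed)
    t = 0.0
    cap = out_t.shape[0]
    k = 0
    out_t[k] = 0.0
    out_s[k, 0] = n1
    out_s[k, 1] = s1
    out_s[k, 2] = n2
    out_s[k, 3] = s2
    out_s[k, 4] = Ncur
    k += 1
    while True:
        ev, total = _draw_event(n1, s1, n2, s2, Ncur, K, rg, b1, b2, de1, de2,
                                dp1, dp2, d1, d2, a1, a2)
        if ev < 0:
            return k, True, False
        t_new = t - math.log(np.random.random()) / total
        if t_new > t_max:
            return k, False, False
        n1, s1, n2, s2, Ncur = _apply(ev, n1, s1, n2, s2, Ncur, rho1, rho2)
        t = t_new
        if k >= cap:
            return k, False, True
        out_t[k] = t
        out_s[k, 0] = n1
        out_s[k, 1] = s1
        out_s[k, 2] = n2
        out_s[k, 3] = s2
        out_s[k, 4] = Ncur
        k += 1


@njit(cache=True)
def _ssa_clonality(n1, s1, n2, s2, Ncur, b1, b2, de1, de2, dp1, dp2,
                   d1, d2, a1, a2, rho1, rho2, sigma, t_max, seed):
    """Run until the mutant reaches marrow clonality >= sigma (outcome 1),
    goes extinct (outcome 0), total extinction (outcome -1) or the time
    horizon (outcome 2).  Returns (outcome, time).  Clonality is checked
    at event times."""
    np.random.seed(seed)
    t = 0.0
    while True:
        if n2 + s2 == 0:
            if n1 + s1 == 0:
                return -1, t
            return 0, t
        if n1 + n2 > 0 and n2 >= sigma * (n1 + n2):
            return 1, t
        ev, total = _draw_event(n1, s1, n2, s2, Ncur, Ncur, 0.0, b1, b2,
                                de1, de2, dp1, dp2, d1, d2, a1, a2)
        if ev < 0:
            return -1, t
        t_new = t - math.log(np.random.random()) / total
        if t_new > t_max:
            return 2, t
        n1, s1, n2, s2, Ncur = _apply(ev, n1, s1, n2, s2, Ncur, rho1, rho2)
        t = t_new


@njit(cache=True)
def _ssa_reconstitution(s0, Ncur, b, de, dp, d, a, rho, threshold, t_max, seed):
    """Single species from an empty marrow with ``s0`` blood cells; run
    until total extinction (0) or total population >= threshold (1)."""
    np.random.seed(seed)
    n = 0
    s = s0
    t = 0.0
    while True:
        tot = n + s
        if tot == 0:
            return 0, t
        if tot >= threshold:
            return 1, t
        ev, total = _draw_event(n, s, 0, 0, Ncur, Ncur, 0.0, b, 0.0, de, 0.0,
                                dp, 0.0, d, 0.0, a, 0.0)
        if ev < 0:
            return 0, t
        t_new = t - math.log(np.random.random()) / total
        if t_new > t_max:
            return 2, t
        n, s, _, _, Ncur = _apply(ev, n, s, 0, 0, Ncur, rho, 0.0)
        t = t_new


# --- Python-facing API ------------------------------------------------------

def _rate_args(params: ModelParameters):
    return (params.beta1, params.beta2, params.delta1, params.delta2,
            params.delta_niche1, params.delta_niche2, params.d1, params.d2,
            params.a1, params.a2)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate kernel seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def simulate(initial: SystemState, params: ModelParameters, horizon: float,
             seed: int, growth: Optional[GrowthConfig] = None,
             t_grid: Optional[Sequence[float]] = None,
             max_events: int = 5_000_000) -> Trajectory:
    """Exact SSA trajectory over ``[0, horizon]`` days.

    By default every event is recorded (up to ``max_events``); pass
    ``t_grid`` to down-sample onto a fixed grid instead.  Identical seeds
    give identical trajectories.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    Ncur = initial.N_current if initial.N_current is not None else \
        (growth.N0 if growth is not None else params.N)
    if initial.n1 + initial.n2 > Ncur:
        raise ValueError("initial occupied niches exceed the niche count")
    K = growth.K if growth is not None else Ncur
    rg = growth.r_per_day if growth is not None else 0.0
    args = (initial.n1, initial.s1, initial.n2, initial.s2, Ncur, K, rg,
            *_rate_args(params), params.rho1, params.rho2)
    if t_grid is not None:
        grid = np.asarray(t_grid, dtype=np.float64)
        if grid.ndim != 1 or np.any(np.diff(grid) < 0) or grid[0] < 0:
            raise ValueError("t_grid must be a non-decreasing 1-D array of times >= 0")
        out = np.empty((grid.shape[0], 5), dtype=np.int64)
        absorbed, _ = _ssa_grid(*args, grid, out, int(seed))
        t = grid
    else:
        out_t = np.empty(max_events + 1, dtype=np.float64)
        out = np.empty((max_events + 1, 5), dtype=np.int64)
        k, absorbed, truncated = _ssa_events(*args, float(horizon), out_t, out, int(seed))
        if truncated:
            raise RuntimeError(
                f"event-exact recording exceeded max_events={max_events}; "
                "use t_grid down-sampling or raise the cap")
        t = out_t[:k]
        out = out[:k]
    return Trajectory(t=np.array(t), n1=out[:, 0].copy(), s1=out[:, 1].copy(),
                      n2=out[:, 2].copy(), s2=out[:, 3].copy(),
                      N_current=out[:, 4].copy(), seed=int(seed), params=params,
                      absorbed=bool(absorbed))


def host_equilibrium(params: ModelParameters) -> tuple[float, float]:
    """Single-species deterministic equilibrium ``(n*, s*)`` implied by the
    species-1 rates (no in-niche death)."""
    b, de, d, a = params.beta1, params.delta1, params.d1, params.a1
    n_star = params.N * (1.0 - d * de / (a * b))
    if n_star <= 0:
        raise ValueError("rates imply an empty marrow at equilibrium")
    s_star = d * n_star * params.N / (a * (params.N - n_star))
    return n_star, s_star


@dataclass(frozen=True)
class EnsembleHitting:
    """Outcome of an ensemble of absorption runs."""

    successes: int
    failures: int
    censored: int
    times: np.ndarray  # hitting times of the successful replicates, days
    seed: int

    @property
    def reps(self) -> int:
        return self.successes + self.failures + self.censored

    @property
    def estimate(self) -> float:
        return self.successes / self.reps

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Clopper-Pearson binomial interval for the success probability."""
        k, n = self.successes, self.reps
        alpha = 1.0 - level
        lo = 0.0 if k == 0 else _beta_dist.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else _beta_dist.ppf(1 - alpha / 2, k + 1, n - k)
        return float(lo), float(hi)


def ensemble_hitting(initial: SystemState, params: ModelParameters, sigma: float,
                     reps: int, seed: int, t_max: float = 1e9) -> EnsembleHitting:
    """Run ``reps`` independent SSA replicates from ``initial`` until the
    mutant reaches marrow clonality >= ``sigma`` or goes extinct."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < sigma <= 1:
        raise ValueError(f"sigma must lie in (0, 1], got {sigma}")
    Ncur = initial.N_current if initial.N_current is not None else params.N
    seeds = _spawn_seeds(seed, reps)
    succ = fail = cens = 0
    times = []
    for r in range(reps):
        out, t = _ssa_clonality(initial.n1, initial.s1, initial.n2, initial.s2,
                                Ncur, *_rate_args(params), params.rho1,
                                params.rho2, float(sigma), float(t_max),
                                int(seeds[r]))
        if out == 1:
            succ += 1
            times.append(t)
        elif out == 2:
            cens += 1
        else:
            fail += 1
    return EnsembleHitting(successes=succ, failures=fail, censored=cens,
                           times=np.asarray(times), seed=int(seed))


def fixation_probability_mc(dose: int, params: ModelParameters, sigma: float,
                            reps: int, seed: int,
                            host_state: Optional[tuple[float, float]] = None,
                            t_max: float = 1e9) -> EnsembleHitting:
    """Monte-Carlo estimate of the probability that ``dose`` donor cells,
    injected into the blood of a host at equilibrium, reach marrow
    clonality >= ``sigma`` before dying out."""
    if dose < 1:
        raise ValueError("dose must be >= 1")
    if host_state is None:
        host_state = host_equilibrium(params)
    n1 = int(round(host_state[0]))
    s1 = int(round(host_state[1]))
    initial = SystemState(n1=n1, s1=s1, n2=0, s2=int(dose))
    return ensemble_hitting(initial, params, sigma, reps, seed, t_max=t_max)


def time_to_clonality_mc(dose: int, params: ModelParameters, sigma: float,
                         reps: int, seed: int,
                         host_state: Optional[tuple[float, float]] = None,
                         t_max: float = 1e9):
    """Mean and SD of the conditional hitting time over successful
    replicates; returns (mean_days, sd_days, ensemble)."""
    ens = fixation_probability_mc(dose, params, sigma, reps, seed,
                                  host_state=host_state, t_max=t_max)
    if ens.successes < 10:
        warnings.warn(
            f"only {ens.successes} of {reps} replicates reached sigma={sigma}; "
            "timing statistics are unreliable", stacklevel=2)
    if ens.successes == 0:
        return math.nan, math.nan, ens
    mean = float(np.mean(ens.times))
    sd = float(np.std(ens.times, ddof=1)) if ens.successes > 1 else 0.0
    return mean, sd, ens


def reconstitution_mc(dose: int, params: ModelParameters, reps: int, seed: int,
                      success_threshold: int = 100,
                      t_max: float = 1e9) -> EnsembleHitting:
    """SSA estimate of the reconstitution probability of a preconditioned
    (empty-marrow) host given ``dose`` donor cells in the blood.

    A replicate succeeds when the total donor population reaches
    ``success_threshold`` cells (after which extinction is negligible) and
    fails on extinction.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return EnsembleHitting(successes=0, failures=reps, censored=0,
                               times=np.empty(0), seed=int(seed))
    seeds = _spawn_seeds(seed, reps)
    b, de, dpr, d, a, rho = params.species(2)
    succ = fail = cens = 0
    times = []
    for r in range(reps):
        out, t = _ssa_reconstitution(int(dose), params.N, b, de, dpr, d, a, rho,
                                     int(success_threshold), float(t_max),
                                     int(seeds[r]))
        if out == 1:
            succ += 1
            times.append(t)
        elif out == 2:
            cens += 1
        else:
            fail += 1
    return EnsembleHitting(successes=succ, failures=fail, censored=cens,
                           times=np.asarray(times), seed=int(seed))
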