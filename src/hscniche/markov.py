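"""Exact absorption probabilities on truncated state spaces.

For systems small enough to enumerate, the continuous-time Markov chain
can be solved exactly: the embedded jump chain's linear system gives the
probability of hitting one absorbing set before another.  This serves as
an independent oracle for the SSA and for the closed-form reconstitution
probability.

The state space is truncated by capping the total blood population; the
truncation bias is estimated by re-solving with a larger cap.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .parameters import ModelParameters

State = tuple[int, int, int, int]  # (n1, s1, n2, s2)


class StateSpaceTooLargeError(RuntimeError):
    pass


def _transitions(state: State, params: ModelParameters,
                 blood_cap: int) -> list[tuple[State, float]]:
    n1, s1, n2, s2 = state
    N = params.N
    n = n1 + n2
    free = (N - n) / N
    blood = s1 + s2
    out: list[tuple[State, float]] = []

    def add(ns: State, rate: float) -> None:
        if rate > 0:
            out.append((ns, rate))

    for i, (ni, si) in ((1, (n1, s1)), (2, (n2, s2))):
        b, de, dpr, d, a, rho = params.species(i)
        dn = 1 if i == 1 else 0  # species-1 increments
        # reproduction: daughter to niche w.p. rho (if room) else blood
        if ni > 0 and b > 0:
            p_niche = rho if n < N else 0.0
            if p_niche > 0:
                add(_bump(state, i, "n", +1), b * ni * p_niche)
            if blood < blood_cap:
                add(_bump(state, i, "s", +1), b * ni * (1.0 - p_niche))
        if si > 0:
            add(_bump(state, i, "s", -1), de * si)                    # blood death
            add(_bump(state, i, "sn", +1), a * si * free)             # attachment
        if ni > 0:
            if dpr > 0:
                add(_bump(state, i, "n", -1), dpr * ni)               # niche death
            if blood < blood_cap:
                add(_bump(state, i, "ns", +1), d * ni)                # detachment
    return out


def _bump(state: State, i: int, which: str, sign: int) -> State:
    n1, s1, n2, s2 = state
    if which == "n":
        if i == 1:
            n1 += sign
        else:
            n2 += sign
    elif which == "s":
        if i == 1:
            s1 += sign
        else:
            s2 += sign
    elif which == "sn":  # blood -> niche
        if i == 1:
            s1 -= 1
            n1 += 1
        else:
            s2 -= 1
            n2 += 1
    elif which == "ns":  # niche -> blood
        if i == 1:
            n1 -= 1
            s1 += 1
        else:
            n2 -= 1
            s2 += 1
    return (n1, s1, n2, s2)


@dataclass(frozen=True)
class AbsorptionResult:
    probability: float       # P(success before failure) from the initial state
    n_states: int
    blood_cap: int
    truncation_bias: float | None = None  # |p(cap) - p(cap + 5)| when requested


def _classify_clonality(sigma: float) -> Callable[[State], int]:
    def classify(state: State) -> int:
        n1, s1, n2, s2 = state
        if n1 + n2 > 0 and n2 >= sigma * (n1 + n2):
            return 1
        if n2 + s2 == 0:
            return 0
        return -1  # transient
    return classify


def _classify_threshold(threshold: int) -> Callable[[State], int]:
    def classify(state: State) -> int:
        tot = sum(state)
        if tot >= threshold:
            return 1
        if tot == 0:
            return 0
        return -1
    return classify


def _solve(initial: State, params: ModelParameters, classify, blood_cap: int,
           max_states: int) -> tuple[float, int]:
    index: dict[State, int] = {}
    order: list[State] = []
    queue: deque[State] = deque()

    def visit(s: State) -> int:
        if s not in index:
            if len(index) >= max_states:
                raise StateSpaceTooLargeError(
                    f"reachable truncated state space exceeds {max_states} states")
            index[s] = len(order)
            order.append(s)
            if classify(s) == -1:
                queue.append(s)
        return index[s]

    visit(initial)
    succ: dict[int, list[tuple[int, float]]] = {}
    while queue:
        s = queue.popleft()
        i = index[s]
        succ[i] = [(visit(ns), rate) for ns, rate in _transitions(s, params, blood_cap)]

    kind = np.array([classify(s) for s in order])
    transient = np.nonzero(kind == -1)[0]
    tpos = {int(g): k for k, g in enumerate(transient)}
    rows, cols, vals = [], [], []
    b = np.zeros(transient.shape[0])
    for k, g in enumerate(transient):
        trans = succ[int(g)]
        total = sum(rate for _, rate in trans)
        if total <= 0:
            # dead-end transient (should not occur: all-zero states classify 0)
            continue
        rows.append(k)
        cols.append(k)
        vals.append(1.0)
        for j, rate in trans:
            p = rate / total
            if kind[j] == 1:
                b[k] += p
            elif kind[j] == -1:
                rows.append(k)
                cols.append(tpos[j])
                vals.append(-p)
    A = csr_matrix((vals, (rows, cols)), shape=(len(transient),) * 2)
    h = spsolve(A, b)
    k0 = classify(initial)
    if k0 == 1:
        return 1.0, len(order)
    if k0 == 0:
        return 0.0, len(order)
    return float(h[tpos[index[initial]]]), len(order)


def brute_force_fixation(initial: State, params: ModelParameters,
                         sigma: float = 1.0, blood_cap: int = 20,
                         max_states: int = 200_000,
                         report_bias: bool = False) -> AbsorptionResult:
    """Exact probability that species 2 reaches marrow clonality >= sigma
    before going extinct, from ``initial = (n1, s1, n2, s2)``.

    Intended for tiny systems (N <= ~4 for two species); raises
    :class:`StateSpaceTooLargeError` beyond ``max_states`` reachable states.
    """
    classify = _classify_clonality(sigma)
    p, ns = _solve(initial, params, classify, blood_cap, max_states)
    bias = None
    if report_bias:
        p2, _ = _solve(initial, params, classify, blood_cap + 5, max_states)
        bias = abs(p - p2)
    return AbsorptionResult(probability=p, n_states=ns, blood_cap=blood_cap,
                            truncation_bias=bias)


def brute_force_reconstitution(dose: int, params: ModelParameters,
                               success_threshold: int = 100,
                               blood_cap: int = 150,
                               max_states: int = 200_000,
                               report_bias: bool = False) -> AbsorptionResult:
    """Exact probability that a single-species population started as
    ``dose`` blood cells in an empty marrow reaches ``success_threshold``
    total cells before extinction.

    Uses species-2 rates; species 1 is absent so the reachable state space
    stays two-dimensional and moderate niche counts remain tractable.
    """
    initial: State = (0, 0, 0, int(dose))
    classify = _classify_threshold(success_threshold)
    p, ns = _solve(initial, params, classify, blood_cap, max_states)
    bias = None
    if report_bias:
        p2, _ = _solve(initial, params, classify, blood_cap + 5, max_states)
        bias = abs(p - p2)
    return AbsorptionResult(probability=p, n_states=ns, blood_cap=blood_cap,
                            truncation_bias=bias)
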