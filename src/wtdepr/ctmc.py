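"""Continuous-time Markov chain benchmark: Gillespie simulation and lumping.

A driven six-state CTMC on two parallel branches (states 1, 2, 3 and their
indistinguishable primed twins 1', 2', 3') carries a net cycle current that
mimics the directional X1-X2 current of the hair bundle.  Lumping each
pair {i, i'} into one observed macrostate yields a linear three-state chain
with zero net current whose irreversibility survives only in the
direction-dependent waiting-time distributions — the situation the
semi-Markov estimator is built for.  The exact Schnakenberg entropy
production of the microscopic chain serves as the total-EPR oracle that
the waiting-time bound must stay below.

Rates are per second; all dwell times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse.csgraph import connected_components

from wtdepr.chains import JumpChain

__all__ = [
    "CTMCSpec",
    "default_six_state_spec",
    "gillespie_simulate",
    "stationary_distribution",
    "schnakenberg_epr",
    "lump_trajectory",
]


@dataclass(frozen=True)
class CTMCSpec:
    """Edge-list specification of a CTMC with an observation (lump) map.

    ``states`` are ordered labels, ``edges`` are (from_label, to_label,
    rate) with strictly positive rates and no self-edges, and ``lump_map``
    sends every microstate label to an integer observed macrostate.
    """

    states: tuple
    edges: tuple
    lump_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = list(self.states)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels")
        for frm, to, rate in self.edges:
            if frm not in labels or to not in labels:
                raise ValueError(f"edge ({frm}, {to}) references unknown state")
            if frm == to:
                raise ValueError("self-edges are not allowed")
            if not rate > 0:
                raise ValueError(f"rate for edge ({frm}, {to}) must be > 0, got {rate}")
        if self.lump_map and set(self.lump_map) != set(labels):
            raise ValueError("lump_map must cover every state")
        object.__setattr__(self, "states", tuple(labels))
        object.__setattr__(self, "edges", tuple((f, t, float(r)) for f, t, r in self.edges))

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        """Dense matrix W with W[i, j] the rate of i -> j (zero diagonal)."""
        index = {s: i for i, s in enumerate(self.states)}
        W = np.zeros((self.n_states, self.n_states))
        for frm, to, rate in self.edges:
            W[index[frm], index[to]] += rate
        return W

    def lump_vector(self) -> np.ndarray:
        """Observed macrostate per microstate index."""
        if not self.lump_map:
            raise ValueError("spec has no lump_map")
        return np.array([self.lump_map[s] for s in self.states], dtype=np.int64)


def default_six_state_spec(
    u1: float = 10.0,
    u2: float = 3.0,
    d1: float = 2.0,
    d2: float = 4.0,
    r1: float = 3.0,
    r2: float = 3.0,
    l1: float = 1.0,
    l2: float = 1.0,
    eps_reverse: float = 0.01,
) -> CTMCSpec:
    """Driven six-state unicyclic ladder lumped to a linear 3-state chain.

    The up-branch climbs 1 -> 2 -> 3 with forward rates ``u1, u2`` and
    reverse rates ``l1, l2``; rungs 3 -> 3' and 1' -> 1 (rates ``r1, r2``)
    connect to the down-branch 3' -> 2' -> 1' (rates ``d2, d1``),
    closing one driven cycle.  Edges without a physical reverse rate get a
    small reverse rate ``eps_reverse`` so the Schnakenberg entropy
    production stays finite; ``eps_reverse=0`` gives the strictly one-way
    variant (simulation only, infinite Schnakenberg EPR).  The lump map
    identifies i with i', producing observed macrostates 1, 2, 3.
    """
    edges = [
        ("1", "2", u1),
        ("2", "3", u2),
        ("2", "1", l1),
        ("3", "2", l2),
        ("3", "3p", r1),
        ("3p", "2p", d2),
        ("2p", "1p", d1),
        ("1p", "1", r2),
    ]
    if eps_reverse > 0:
        edges += [
            ("3p", "3", eps_reverse),
            ("2p", "3p", eps_reverse),
            ("1p", "2p", eps_reverse),
            ("1", "1p", eps_reverse),
        ]
    lump = {"1": 1, "2": 2, "3": 3, "1p": 1, "2p": 2, "3p": 3}
    return CTMCSpec(states=("1", "2", "3", "3p", "2p", "1p"), edges=tuple(edges), lump_map=lump)


@njit(cache=True)
def _gillespie_loop(exit_rates, cum_probs, targets, offsets, n_jumps, start, seed):  # pragma: no cover
    np.random.seed(seed)
    states = np.empty(n_jumps + 1, dtype=np.int64)
    dwells = np.empty(n_jumps + 1)
    s = start
    for i in range(n_jumps + 1):
        r = exit_rates[s]
        states[i] = s
        dwells[i] = np.random.exponential(1.0 / r)
        if i == n_jumps:
            break
        u = np.random.random()
        lo = offsets[s]
        hi = offsets[s + 1]
        j = lo
        while j < hi - 1 and u > cum_probs[j]:
            j += 1
        s = targets[j]
    return states, dwells


def gillespie_simulate(spec: CTMCSpec, n_jumps: int, seed: int = 0, start=None) -> JumpChain:
    """Exact stochastic simulation: n_jumps transitions from ``start``.

    Dwell times are exponential with the total exit rate of the current
    state; the next state is chosen proportionally to the outgoing edge
    rates.  Deterministic given ``seed``.  Returned states are microstate
    indices into ``spec.states``.
    """
    if n_jumps <= 0:
        raise ValueError("n_jumps must be positive")
    W = spec.rate_matrix()
    exit_rates = W.sum(axis=1)
    if np.any(exit_rates <= 0):
        dead = [spec.states[i] for i in np.flatnonzero(exit_rates <= 0)]
        raise ValueError(f"absorbing state(s) {dead}: Gillespie simulation cannot proceed")
    # flattened per-state cumulative jump distributions
    offsets = [0]
    targets: list[int] = []
    cum: list[float] = []
    for i in range(spec.n_states):
        row = np.flatnonzero(W[i])
        probs = np.cumsum(W[i, row] / exit_rates[i])
        targets.extend(row.tolist())
        cum.extend(probs.tolist())
        offsets.append(len(targets))
    start_idx = 0 if start is None else list(spec.states).index(start)
    states, dwells = _gillespie_loop(
        exit_rates,
        np.array(cum),
        np.array(targets, dtype=np.int64),
        np.array(offsets, dtype=np.int64),
        int(n_jumps),
        start_idx,
        int(seed),
    )
    return JumpChain(states, dwells, meta={"labels": spec.states})


def stationary_distribution(spec: CTMCSpec) -> np.ndarray:
    """Stationary probability vector of the master equation, pi @ Q = 0.

    Solved by replacing one balance equation with the normalization
    constraint; a chain that is not strongly connected (reducible) is
    rejected because the stationary law would not be unique.
    """
    W = spec.rate_matrix()
    n_comp, _ = connected_components(W > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("chain is reducible: stationary distribution not unique")
    Q = W - np.diag(W.sum(axis=1))
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(spec.n_states)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    if np.any(pi <= 0):
        raise ValueError("stationary solve produced non-positive entries")
    return pi


def schnakenberg_epr(spec: CTMCSpec) -> float:
    """Exact steady-state entropy production, k_B per unit time.

    Sum over ordered pairs of (1/2)(pi_i w_ij - pi_j w_ji)
    ln[(pi_i w_ij)/(pi_j w_ji)]; non-negative, zero iff detailed balance
    holds.  A one-way edge (rate > 0 with zero reverse) makes the entropy
    production formally infinite, reported as ``inf`` rather than raised.
    """
    W = spec.rate_matrix()
    forward = W > 0
    if np.any(forward & ~forward.T):
        return float("inf")
    pi = stationary_distribution(spec)
    total = 0.0
    n = spec.n_states
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                fij = pi[i] * W[i, j]
                fji = pi[j] * W[j, i]
                total += (fij - fji) * np.log(fij / fji)
    return float(total)


def lump_trajectory(micro: JumpChain, lump_map) -> JumpChain:
    """Project a microstate chain through ``lump_map`` and merge repeats.

    ``lump_map`` is either a dict keyed by the labels stored in
    ``micro.meta['labels']`` (or by integer microstate index) or an array
    mapping index -> macrostate.  Consecutive identical macrostates are
    merged by summing their dwell times, so total time is conserved
    exactly and the output has no immediate repeats.
    """
    if isinstance(lump_map, dict):
        labels = micro.meta.get("labels")
        if labels is not None and all(lab in lump_map for lab in labels):
            vec = np.array([lump_map[lab] for lab in labels], dtype=np.int64)
        else:
            vec = np.zeros(int(micro.states.max()) + 1, dtype=np.int64)
            for k, v in lump_map.items():
                vec[int(k)] = int(v)
    else:
        vec = np.asarray(lump_map, dtype=np.int64)
    macro = vec[micro.states]
    change = np.flatnonzero(np.diff(macro)) + 1
    starts = np.concatenate([[0], change])
    states = macro[starts]
    dwells = np.add.reduceat(micro.dwells, starts)
    return JumpChain(states, dwells, meta={"lumped_from": micro.meta.get("labels")})
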