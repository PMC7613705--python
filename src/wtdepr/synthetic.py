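"""Synthetic second-order semi-Markov chains with known ground truth.

Chains are generated directly in the coarse-grained representation: the
next state is drawn from pair-conditioned transition probabilities
``p([ij] -> [jk])`` and the dwell time at the middle state from a named
parametric law attached to the realized triplet ``(i, j, k)``.  Restricting
the law menu to Exponential and Gamma keeps every pairwise
Kullback-Leibler divergence in closed form, so the waiting-time EPR of a
spec is computable exactly and every estimator can be validated without
simulating the physical models.  A symmetric random walk with
direction-independent dwell laws provides the time-reversible null
(EPR_aff = EPR_WTD = 0, MDAF = 1 in expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from wtdepr.chains import JumpChain

__all__ = [
    "SemiMarkovSpec",
    "closed_form_kld",
    "law_mean",
    "generate_chain",
    "analytic_epr_wtd",
    "analytic_epr_aff",
    "reversible_null",
]

_LAW_NAMES = ("exp", "gamma")


def _check_law(law) -> tuple:
    name = law[0]
    if name == "exp":
        _, rate = law
        if rate <= 0:
            raise ValueError("exponential rate must be positive")
        return ("exp", float(rate))
    if name == "gamma":
        _, shape, rate = law
        if shape <= 0 or rate <= 0:
            raise ValueError("gamma shape and rate must be positive")
        return ("gamma", float(shape), float(rate))
    raise ValueError(f"unknown law {name!r}; supported: {_LAW_NAMES}")


def law_mean(law) -> float:
    """Mean dwell time of a law: 1/rate for exp, shape/rate for gamma."""
    law = _check_law(law)
    if law[0] == "exp":
        return 1.0 / law[1]
    return law[1] / law[2]


def _as_gamma(law) -> tuple:
    law = _check_law(law)
    return (1.0, law[1]) if law[0] == "exp" else (law[1], law[2])


def closed_form_kld(law_p, law_q) -> float:
    """Exact D[p || q] in nats between Exponential/Gamma laws.

    Both families reduce to Gamma(shape a, rate b); for those,
    D = (a_p - a_q) psi(a_p) - ln G(a_p) + ln G(a_q)
        + a_q ln(b_p / b_q) + a_p (b_q - b_p) / b_p.
    """
    ap, bp = _as_gamma(law_p)
    aq, bq = _as_gamma(law_q)
    return float(
        (ap - aq) * digamma(ap)
        - gammaln(ap)
        + gammaln(aq)
        + aq * np.log(bp / bq)
        + ap * (bq - bp) / bp
    )


@dataclass(frozen=True)
class SemiMarkovSpec:
    """Full specification of a second-order semi-Markov chain.

    ``transition_prob[(i, j, k)]`` is p([ij] -> [jk]), normalized over k
    for each pair (i, j); ``dwell_law[(i, j, k)]`` names the dwell-time
    law at j for the i -> j -> k passage.
    """

    states: tuple
    transition_prob: dict
    dwell_law: dict
    seed: int = 0

    def __post_init__(self) -> None:
        pair_sums: dict = {}
        for (i, j, k), p in self.transition_prob.items():
            if p < 0:
                raise ValueError("transition probabilities must be non-negative")
            pair_sums[(i, j)] = pair_sums.get((i, j), 0.0) + p
        for pair, s in pair_sums.items():
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities for pair {pair} sum to {s}, not 1")
        for t, p in self.transition_prob.items():
            if p > 0 and t not in self.dwell_law:
                raise ValueError(f"reachable triplet {t} has no dwell law")
        object.__setattr__(
            self, "dwell_law", {t: _check_law(law) for t, law in self.dwell_law.items()}
        )

    @property
    def pairs(self) -> list:
        return sorted({(i, j) for (i, j, _) in self.transition_prob})


def _pair_stationary(spec: SemiMarkovSpec) -> dict:
    """Stationary occupancy R[i, j] of the embedded pair chain."""
    pairs = spec.pairs
    idx = {p: n for n, p in enumerate(pairs)}
    T = np.zeros((len(pairs), len(pairs)))
    for (i, j, k), p in spec.transition_prob.items():
        if p > 0:
            T[idx[(i, j)], idx[(j, k)]] = p
    A = T.T - np.eye(len(pairs))
    A[-1, :] = 1.0
    b = np.zeros(len(pairs))
    b[-1] = 1.0
    R = np.linalg.solve(A, b)
    if np.any(R < -1e-12):
        raise ValueError("pair chain is not irreducible; stationary solve failed")
    R = np.clip(R, 0.0, None)
    R /= R.sum()
    return {p: float(R[idx[p]]) for p in pairs}


def _draw_dwell(law, rng: np.random.Generator) -> float:
    if law[0] == "exp":
        return float(rng.exponential(1.0 / law[1]))
    return float(rng.gamma(law[1], 1.0 / law[2]))


def generate_chain(spec: SemiMarkovSpec, n_jumps: int, seed: int | None = None) -> JumpChain:
    """Sample a chain of ``n_jumps`` transitions from the spec.

    The initial pair is drawn from the stationary pair occupancy, so the
    chain starts in steady state; dwell times for the first and last
    (incomplete) passages carry no triplet label and are set to the mean
    of an applicable law — downstream triplet collection discards them.
    """
    if n_jumps < 2:
        raise ValueError("n_jumps must be >= 2")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    R = _pair_stationary(spec)
    pairs = list(R)
    start = pairs[rng.choice(len(pairs), p=np.array([R[p] for p in pairs]))]

    # per-pair jump tables
    nexts: dict = {}
    for (i, j, k), p in spec.transition_prob.items():
        if p > 0:
            nexts.setdefault((i, j), []).append((k, p))
    cum: dict = {}
    for pair, lst in nexts.items():
        ks, ps = zip(*lst)
        cum[pair] = (np.array(ks), np.cumsum(ps))

    states = [start[0], start[1]]
    dwells = [1.0]  # placeholder dwell for the incomplete first passage
    u = rng.random(n_jumps - 1)
    i, j = start
    for step in range(n_jumps - 1):
        ks, cp = cum[(i, j)]
        k = int(ks[np.searchsorted(cp, u[step] * cp[-1])])
        dwells.append(_draw_dwell(spec.dwell_law[(i, j, k)], rng))
        states.append(k)
        i, j = j, k
    dwells.append(1.0)  # placeholder for the incomplete last passage
    dwells[0] = law_mean(spec.dwell_law[min(spec.dwell_law)])
    dwells[-1] = dwells[0]
    return JumpChain(np.array(states), np.array(dwells), meta={"spec_states": spec.states})


def _triplet_probs(spec: SemiMarkovSpec) -> tuple:
    R = _pair_stationary(spec)
    probs = {
        t: R[(t[0], t[1])] * p for t, p in spec.transition_prob.items() if p > 0
    }
    tau = sum(
        probs[t] * law_mean(spec.dwell_law[t]) for t in probs
    )  # = sum_ij R_ij tau_ij since tau_ij averages over k
    return probs, tau


def analytic_epr_wtd(spec: SemiMarkovSpec) -> float:
    """Exact waiting-time EPR of the spec, k_B per unit time.

    (1/tau) sum_ijk p(ijk) D[law(ijk) || law(kji)] with closed-form KLDs
    and the exact stationary pair occupancy.
    """
    probs, tau = _triplet_probs(spec)
    total = 0.0
    for (i, j, k), p in probs.items():
        rev = (k, j, i)
        if rev not in spec.dwell_law:
            raise ValueError(f"triplet ({i},{j},{k}) reachable but reverse {rev} has no law")
        total += p * closed_form_kld(spec.dwell_law[(i, j, k)], spec.dwell_law[rev])
    return total / tau


def analytic_epr_aff(spec: SemiMarkovSpec) -> float:
    """Exact affinity EPR of the spec, k_B per unit time."""
    probs, tau = _triplet_probs(spec)
    total = 0.0
    for (i, j, k), p in probs.items():
        p_rev = spec.transition_prob.get((k, j, i), 0.0)
        if p_rev == 0.0:
            return float("inf")
        total += p * np.log(spec.transition_prob[(i, j, k)] / p_rev)
    return total / tau


def reversible_null(
    n_states: int, dwell_law=("exp", 1.0), n_jumps: int = 10_000, seed: int = 0
) -> JumpChain:
    """Time-reversible null chain: symmetric walk, direction-blind dwells.

    A symmetric random walk on the linear chain 1..n_states (reflecting
    boundaries) with the same dwell law for every passage through a given
    state.  ``dwell_law`` is one law applied everywhere or a dict keyed by
    state.  By construction EPR_aff = EPR_WTD = 0 and MDAF = 1 in
    expectation.
    """
    if n_states < 3:
        raise ValueError("need at least 3 states")
    laws = (
        {j: _check_law(dwell_law[j]) for j in dwell_law}
        if isinstance(dwell_law, dict)
        else {j: _check_law(dwell_law) for j in range(1, n_states + 1)}
    )
    tp: dict = {}
    dl: dict = {}
    for j in range(1, n_states + 1):
        neighbours = [x for x in (j - 1, j + 1) if 1 <= x <= n_states]
        prev_candidates = neighbours
        for i in prev_candidates:
            for k in neighbours:
                tp[(i, j, k)] = 1.0 / len(neighbours)
                dl[(i, j, k)] = laws[j]
    spec = SemiMarkovSpec(
        states=tuple(range(1, n_states + 1)), transition_prob=tp, dwell_law=dl, seed=seed
    )
    return generate_chain(spec, n_jumps, seed=seed)
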