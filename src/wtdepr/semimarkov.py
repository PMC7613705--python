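"""Irreversibility estimation from second-order semi-Markov statistics.

A jump chain observed through coarse-graining is generally not Markov: the
waiting time at a state ``j`` and the next state depend on the previously
visited state.  Collecting statistics over passages ``i -> j -> k``
(triplets) captures this second-order structure.  Two additive
contributions bound the total entropy production rate from below:

* the affinity EPR — net-flux asymmetry of the pair-transition
  probabilities,

      EPR_aff = (1/tau) sum_ijk p(ijk) ln[ p([ij]->[jk]) / p([kj]->[ji]) ],

  identically zero on a linear (cycle-free) topology; and

* the waiting-time-distribution EPR — broken time-reversal symmetry of
  the conditional dwell densities,

      EPR_WTD = (1/tau) sum_ijk p(ijk) D[ Psi(t|ijk) || Psi(t|kji) ],

  where ``Psi(t|ijk)`` is the density of the dwell time at ``j`` during an
  ``i -> j -> k`` passage, ``p(ijk) = R_[ij] p([ij]->[jk])`` and ``tau``
  the mean step duration.

The mean dwell-time asymmetry factor (MDAF) is the first-cumulant
footprint of the same asymmetry: the ratio of mean reverse to mean forward
dwell times, 1 under time reversibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from wtdepr.chains import JumpChain

__all__ = [
    "TripletStats",
    "KLDResult",
    "EPRReport",
    "collect_triplets",
    "epr_aff",
    "kld_estimate",
    "epr_wtd",
    "mdaf",
    "bootstrap_errors",
]


@dataclass(frozen=True)
class TripletStats:
    """Second-order statistics of a jump chain, indexed by (i, j, k).

    ``counts[(i, j, k)]`` — observed i -> j -> k passages;
    ``dwell_samples[(i, j, k)]`` — dwell times at j during those passages, s;
    ``R[(i, j)]`` — normalized occupancy of the pair state [previous=i, current=j];
    ``tau_ij[(i, j)]`` — mean dwell at j given arrival from i, s;
    ``transition_prob[(i, j, k)]`` — p([ij] -> [jk]);
    ``tau`` — mean step duration sum_ij R[ij] tau_ij, s.
    """

    counts: dict
    dwell_samples: dict
    R: dict
    tau_ij: dict
    transition_prob: dict
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("mean step duration must be positive")
        for t, c in self.counts.items():
            if len(self.dwell_samples[t]) != c:
                raise ValueError(f"counts inconsistent with samples for triplet {t}")

    @property
    def states(self) -> list:
        return sorted({s for (i, j, k) in self.counts for s in (i, j, k)})


def collect_triplets(chain: JumpChain) -> TripletStats:
    """Gather counts, occupancies, mean dwells and dwell samples per triplet.

    Every internal position of the chain contributes one passage
    ``i -> j -> k`` with the dwell recorded at ``j``; the first and last
    (incomplete) passages are discarded.
    """
    s = chain.states
    d = chain.dwells
    if len(s) < 3:
        raise ValueError("chain too short: need at least 3 states (2 jumps) for one triplet")
    trip = np.stack([s[:-2], s[1:-1], s[2:]], axis=1)
    dwell = d[1:-1]
    n_max = int(s.max()) + 1
    code = (trip[:, 0] * n_max + trip[:, 1]) * n_max + trip[:, 2]
    order = np.argsort(code, kind="stable")
    code_sorted = code[order]
    dwell_sorted = dwell[order]
    uniq, starts, cnts = np.unique(code_sorted, return_index=True, return_counts=True)

    counts: dict = {}
    dwell_samples: dict = {}
    pair_counts: dict = {}
    pair_dwell_sum: dict = {}
    for u, st, c in zip(uniq, starts, cnts):
        k = int(u % n_max)
        ij = int(u // n_max)
        j = int(ij % n_max)
        i = int(ij // n_max)
        t = (i, j, k)
        counts[t] = int(c)
        samples = dwell_sorted[st : st + c]
        dwell_samples[t] = samples
        pair_counts[(i, j)] = pair_counts.get((i, j), 0) + int(c)
        pair_dwell_sum[(i, j)] = pair_dwell_sum.get((i, j), 0.0) + float(samples.sum())

    total_pairs = sum(pair_counts.values())
    R = {p: c / total_pairs for p, c in pair_counts.items()}
    tau_ij = {p: pair_dwell_sum[p] / pair_counts[p] for p in pair_counts}
    transition_prob = {
        (i, j, k): counts[(i, j, k)] / pair_counts[(i, j)] for (i, j, k) in counts
    }
    tau = sum(R[p] * tau_ij[p] for p in R)
    return TripletStats(
        counts=counts,
        dwell_samples=dwell_samples,
        R=R,
        tau_ij=tau_ij,
        transition_prob=transition_prob,
        tau=float(tau),
    )


def triplet_probability(stats: TripletStats, triplet: tuple) -> float:
    """p(ijk) = R_[ij] * p([ij] -> [jk])."""
    i, j, k = triplet
    return stats.R[(i, j)] * stats.transition_prob[triplet]


def epr_aff(stats: TripletStats) -> float:
    """Affinity EPR (net-flux contribution), k_B / s.

    Zero exactly when every forward pair-transition probability equals its
    reverse; infinite (with a warning) when a forward transition has no
    observed reverse, which on finite data usually signals undersampling
    rather than a true one-way transition.
    """
    total = 0.0
    for (i, j, k), p_fwd in stats.transition_prob.items():
        rev = (k, j, i)
        p_rev = stats.transition_prob.get(rev)
        if p_rev is None or p_rev == 0.0:
            warnings.warn(
                f"forward passage {i}->{j}->{k} has no observed reverse {k}->{j}->{i}; "
                "affinity EPR is unbounded on this sample",
                UserWarning,
                stacklevel=2,
            )
            return float("inf")
        total += triplet_probability(stats, (i, j, k)) * np.log(p_fwd / p_rev)
    return total / stats.tau


@dataclass(frozen=True)
class KLDResult:
    """One Kullback-Leibler divergence estimate, nats."""

    value: float  # clipped to >= 0
    raw: float  # before clipping
    stderr: float
    n_p: int
    n_q: int
    method: str


def _knn_kld(p: np.ndarray, q: np.ndarray, k: int) -> float:
    """k-nearest-neighbour KLD estimate (1-D Wang-Kulkarni-Verdu form)."""
    n, m = len(p), len(q)
    pc = p.reshape(-1, 1)
    qc = q.reshape(-1, 1)
    rho = cKDTree(pc).query(pc, k=k + 1)[0][:, -1]  # k-th NN excluding self
    nu = cKDTree(qc).query(pc, k=k)[0]
    nu = nu[:, -1] if nu.ndim == 2 else nu
    return float(np.mean(np.log(nu / rho)) + np.log(m / (n - 1)))


def _histogram_kld(p: np.ndarray, q: np.ndarray, n_bins: int) -> float:
    """Shared-bin histogram KLD on a log-time axis, 0.5 pseudo-count smoothed."""
    pooled = np.concatenate([p, q])
    lo, hi = np.log(pooled.min()), np.log(pooled.max())
    if hi <= lo:
        return 0.0
    bins = np.linspace(lo, hi, n_bins + 1)
    hp = np.histogram(np.log(p), bins=bins)[0] + 0.5
    hq = np.histogram(np.log(q), bins=bins)[0] + 0.5
    hp = hp / hp.sum()
    hq = hq / hq.sum()
    return float(np.sum(hp * np.log(hp / hq)))


def _dither(samples: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Break exact ties (lattice-valued dwells) with sub-resolution jitter."""
    uniq = np.unique(samples)
    if len(uniq) == len(samples):
        return samples
    gap = np.diff(uniq).min() if len(uniq) > 1 else samples[0]
    return samples + rng.uniform(-0.5, 0.5, size=len(samples)) * gap


def kld_estimate(
    samples_p: np.ndarray,
    samples_q: np.ndarray,
    method: str = "knn",
    k: int = 5,
    n_bins: int = 30,
    n_boot: int = 0,
    seed: int = 0,
    min_samples: int = 50,
) -> KLDResult:
    """Estimate D[p || q] in nats from two sets of positive dwell samples.

    ``method='knn'`` uses the k-nearest-neighbour divergence estimator
    (default k = 5), with deterministic sub-resolution dithering when the
    samples sit on a lattice (dwells from a uniformly sampled trajectory
    are integer multiples of the sampling interval, and the estimator
    needs distinct order statistics).  ``method='hist'`` uses a shared-bin
    histogram on the log-time axis.  Raw estimates below zero are clipped
    to 0 (the divergence is non-negative); the raw value is retained.
    ``n_boot > 0`` adds a bootstrap standard error.
    """
    p = np.asarray(samples_p, dtype=float).ravel()
    q = np.asarray(samples_q, dtype=float).ravel()
    if len(p) < min_samples or len(q) < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples on both sides, got {len(p)} and {len(q)}"
        )
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("dwell samples must be strictly positive")
    rng = np.random.default_rng(seed)
    if method == "knn":
        p_use, q_use = _dither(p, rng), _dither(q, rng)
        estimator = lambda a, b: _knn_kld(a, b, k)  # noqa: E731
    elif method == "hist":
        p_use, q_use = p, q
        estimator = lambda a, b: _histogram_kld(a, b, n_bins)  # noqa: E731
    else:
        raise ValueError("method must be 'knn' or 'hist'")
    raw = estimator(p_use, q_use)
    stderr = 0.0
    if n_boot > 0:
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pb = rng.choice(p_use, size=len(p_use), replace=True)
            qb = rng.choice(q_use, size=len(q_use), replace=True)
            if method == "knn":
                # resampling duplicates samples; re-dither to keep order statistics distinct
                pb, qb = _dither(pb, rng), _dither(qb, rng)
            boots[b] = estimator(pb, qb)
        stderr = float(boots.std(ddof=1))
    return KLDResult(
        value=max(raw, 0.0), raw=raw, stderr=stderr, n_p=len(p), n_q=len(q), method=method
    )


@dataclass(frozen=True)
class EPRReport:
    """Irreversibility estimates for one jump chain."""

    epr_aff: float  # k_B / s
    epr_wtd: float  # k_B / s
    mdaf: float  # dimensionless
    per_triplet_kld: dict = field(default_factory=dict)  # (i,j,k) -> nats
    per_triplet_mdaf: dict = field(default_factory=dict)  # (i,j,k) with i<k -> ratio
    stderr_epr_aff: float = 0.0
    stderr_epr_wtd: float = 0.0
    stderr_mdaf: float = 0.0
    excluded_triplets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epr_wtd < 0:
            raise ValueError("EPR_WTD must be non-negative")


def epr_wtd(
    stats: TripletStats,
    method: str = "knn",
    k: int = 5,
    n_bins: int = 30,
    min_samples: int = 50,
    n_boot: int = 0,
    seed: int = 0,
):
    """Waiting-time-distribution EPR, k_B / s, with per-triplet decomposition.

    For every pass-through triplet (i, j, k) with i != k and an observed
    reverse partner, estimates D[Psi(t|ijk) || Psi(t|kji)] and accumulates
    (1/tau) sum p(ijk) D.  Reflection triplets (i = k) compare a density
    with itself and contribute exactly zero.  Triplets whose own or
    reverse sample set is below ``min_samples`` are excluded and listed.
    Returns ``(value, per_triplet_kld, excluded, stderr)``.
    """
    per_triplet: dict = {}
    excluded: list = []
    total = 0.0
    var_total = 0.0
    usable = 0
    for t in sorted(stats.counts):
        i, j, kk = t
        if i == kk:
            continue
        rev = (kk, j, i)
        fwd_samples = stats.dwell_samples[t]
        rev_samples = stats.dwell_samples.get(rev)
        if rev_samples is None:
            excluded.append((t, "no reverse passages observed"))
            continue
        if len(fwd_samples) < min_samples or len(rev_samples) < min_samples:
            excluded.append(
                (t, f"insufficient samples ({len(fwd_samples)} fwd, {len(rev_samples)} rev)")
            )
            continue
        res = kld_estimate(
            fwd_samples,
            rev_samples,
            method=method,
            k=k,
            n_bins=n_bins,
            n_boot=n_boot,
            seed=seed + hash(t) % 100_000,
            min_samples=min_samples,
        )
        per_triplet[t] = res.value
        weight = triplet_probability(stats, t) / stats.tau
        total += weight * res.value
        var_total += (weight * res.stderr) ** 2
        usable += 1
    if usable == 0:
        raise ValueError(
            "no usable triplet pair: every pass-through triplet lacks a sampled reverse "
            f"partner or has fewer than {min_samples} samples"
        )
    return total, per_triplet, excluded, float(np.sqrt(var_total))


def mdaf(
    stats: TripletStats,
    min_samples: int = 50,
    normalizer: str = "pairs",
    n_boot: int = 200,
    seed: int = 0,
):
    """Mean dwell-time asymmetry factor: total plus per-pair map.

    For each direction-paired pass-through triplet the ratio
    ``<tau_kji> / <tau_ijk>`` is taken with the upward passage
    (increasing state index, i < k) in the denominator.  The total is the
    average of per-pair ratios over the pairs actually observed
    (``normalizer='pairs'``); ``normalizer='n_states'`` divides the sum by
    the number of coarse-grained states instead.  Standard error by
    bootstrap over the dwell samples.  Returns
    ``(total, per_pair, excluded, stderr)``.
    """
    rng = np.random.default_rng(seed)
    per_pair: dict = {}
    per_pair_var: dict = {}
    excluded: list = []
    for t in sorted(stats.counts):
        i, j, k = t
        if i >= k:  # one entry per unordered direction pair, keyed by the upward triplet
            continue
        rev = (k, j, i)
        up = stats.dwell_samples[t]
        down = stats.dwell_samples.get(rev)
        if down is None:
            excluded.append((t, "downward direction never observed"))
            continue
        if len(up) < min_samples or len(down) < min_samples:
            excluded.append((t, f"insufficient samples ({len(up)} up, {len(down)} down)"))
            continue
        ratio = float(down.mean() / up.mean())
        per_pair[t] = ratio
        if n_boot > 0:
            boots = np.empty(n_boot)
            for b in range(n_boot):
                boots[b] = rng.choice(down, len(down)).mean() / rng.choice(up, len(up)).mean()
            per_pair_var[t] = float(boots.var(ddof=1))
        else:
            per_pair_var[t] = 0.0
    if not per_pair:
        raise ValueError("no direction-paired pass-through triplet with enough samples")
    if normalizer == "pairs":
        denom = len(per_pair)
    elif normalizer == "n_states":
        denom = len(stats.states)
    else:
        raise ValueError("normalizer must be 'pairs' or 'n_states'")
    total = sum(per_pair.values()) / denom
    stderr = float(np.sqrt(sum(per_pair_var.values())) / denom)
    return total, per_pair, excluded, stderr


def bootstrap_errors(
    chain: JumpChain,
    estimator,
    n_boot: int = 200,
    n_blocks: int = 50,
    seed: int = 0,
) -> float:
    """Circular block-bootstrap standard error of ``estimator(chain)``.

    The chain is cut into ``n_blocks`` contiguous jump blocks; each
    bootstrap replicate concatenates ``n_blocks`` blocks drawn with
    replacement (merging equal states at the seams) and re-runs the
    estimator.  Deterministic given ``seed``.
    """
    n = len(chain)
    if n < n_blocks:
        raise ValueError(f"chain has {n} records, fewer than {n_blocks} blocks")
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    blocks = [(edges[b], edges[b + 1]) for b in range(n_blocks)]
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for b in range(n_boot):
        picks = rng.integers(0, n_blocks, size=n_blocks)
        parts_s = [chain.states[lo:hi] for lo, hi in (blocks[p] for p in picks)]
        parts_d = [chain.dwells[lo:hi] for lo, hi in (blocks[p] for p in picks)]
        s = np.concatenate(parts_s)
        d = np.concatenate(parts_d)
        # merge seam repeats so the resample is a valid jump chain
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], change])
        s_merged = s[starts]
        d_merged = np.add.reduceat(d, starts)
        values[b] = estimator(JumpChain(s_merged, d_merged, dict(chain.meta)))
    return float(values.std(ddof=1))
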