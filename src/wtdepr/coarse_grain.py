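"""Spatial coarse-graining of the observed coordinate into discrete states.

The observed tip position is thresholded into ``N`` bins (states) whose
widths follow one of two schemes: ``equal`` (all widths equal, ratios
1:1:...:1) or ``unequal`` (wide boundary bins, narrow interior bins, with
width ratios 1 : 1/(N-2) : ... : 1/(N-2) : 1 for N >= 4 and 1:1:1 for
N = 3).  The unequal scheme concentrates resolution in the interior of the
oscillation where irregular trajectories spend most of their time, so the
boundary states retain enough statistics.  Runs of identical bin labels
are merged into dwell intervals, giving a jump chain with a strictly
linear topology when the sampling is fine enough to catch every crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from wtdepr.chains import JumpChain

__all__ = [
    "Partition",
    "partition_edges",
    "partition_from_series",
    "discretize",
    "validate_linear",
    "LinearityReport",
    "check_triplet_coverage",
]


@dataclass(frozen=True)
class Partition:
    """Binning of a reference interval into N coarse-grained states."""

    n_states: int
    scheme: str
    edges: np.ndarray  # N - 1 strictly increasing interior boundaries, nm
    span: tuple  # (low, high) reference interval, nm

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        low, high = self.span
        if self.n_states < 3:
            raise ValueError("n_states must be >= 3")
        if self.scheme not in ("equal", "unequal"):
            raise ValueError("scheme must be 'equal' or 'unequal'")
        if len(edges) != self.n_states - 1:
            raise ValueError("need exactly n_states - 1 interior edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if edges[0] <= low or edges[-1] >= high:
            raise ValueError("edges must lie strictly inside the span")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "span", (float(low), float(high)))


def width_ratios(n_states: int, scheme: str) -> np.ndarray:
    """Relative bin widths for a scheme; sums are not normalized."""
    if n_states < 3:
        raise ValueError("n_states must be >= 3 (the minimum useful partition)")
    if scheme == "equal":
        return np.ones(n_states)
    if scheme == "unequal":
        if n_states == 3:
            return np.ones(3)
        inner = 1.0 / (n_states - 2)
        return np.array([1.0] + [inner] * (n_states - 2) + [1.0])
    raise ValueError("scheme must be 'equal' or 'unequal'")


def partition_edges(low: float, high: float, n_states: int, scheme: str = "equal") -> Partition:
    """Build a Partition with bin widths proportional to the scheme's ratios."""
    if not high > low:
        raise ValueError("high must exceed low")
    ratios = width_ratios(n_states, scheme)
    widths = ratios / ratios.sum() * (high - low)
    edges = low + np.cumsum(widths)[:-1]
    return Partition(n_states=n_states, scheme=scheme, edges=edges, span=(low, high))


def partition_from_series(
    x1: np.ndarray, n_states: int, scheme: str = "equal", span_mode: str = "minmax"
) -> Partition:
    """Partition with the reference span taken from the data.

    ``span_mode='minmax'`` uses the empirical min/max of the series;
    ``'mean3std'`` uses mean +/- 3 std, clipped to the empirical min/max.
    """
    x1 = np.asarray(x1, dtype=float)
    lo, hi = float(x1.min()), float(x1.max())
    if span_mode == "mean3std":
        m, s = float(x1.mean()), float(x1.std())
        lo, hi = max(lo, m - 3 * s), min(hi, m + 3 * s)
    elif span_mode != "minmax":
        raise ValueError("span_mode must be 'minmax' or 'mean3std'")
    return partition_edges(lo, hi, n_states, scheme)


def discretize(times: np.ndarray, x1: np.ndarray, partition: Partition) -> JumpChain:
    """Threshold a uniformly sampled series into a jump chain.

    Each sample is assigned the bin containing it (half-open lower-
    inclusive bins, last bin closed; values outside the span fall into the
    nearest boundary bin), consecutive identical assignments are merged,
    and each dwell is the sample count times the sampling interval.
    States are labelled 1..N; times and dwells are in seconds.

    A series that never leaves one bin yields a single-record chain with
    ``meta['degenerate'] = True``, unusable for triplet statistics.
    """
    times = np.asarray(times, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if len(times) != len(x1) or len(times) < 2:
        raise ValueError("times and x1 must be equal-length with >= 2 samples")
    if not np.all(np.isfinite(x1)):
        raise ValueError("x1 must be finite")
    dt = float(times[1] - times[0])
    if dt <= 0 or not np.allclose(np.diff(times), dt, rtol=1e-6, atol=1e-12):
        raise ValueError("sampling must be uniform")
    assignment = np.searchsorted(partition.edges, x1, side="right")  # 0..N-1, clamps outside span

    change = np.flatnonzero(np.diff(assignment)) + 1
    starts = np.concatenate([[0], change])
    counts = np.diff(np.concatenate([starts, [len(assignment)]]))
    states = assignment[starts] + 1
    dwells = counts * dt
    meta = {
        "partition": partition,
        "dt_sample_s": dt,
        "degenerate": len(states) == 1,
    }
    return JumpChain(states, dwells, meta=meta)


@dataclass(frozen=True)
class LinearityReport:
    """Outcome of the linear-topology check on a jump chain."""

    n_jumps: int
    n_nonadjacent: int
    fraction_nonadjacent: float
    ok: bool
    threshold: float


def validate_linear(chain: JumpChain, n_states: int, threshold: float = 1e-3) -> LinearityReport:
    """Report the fraction of jumps that skip a bin (|delta state| > 1).

    Skipped-bin jumps indicate under-sampling of the continuous
    trajectory; downstream estimation refuses chains whose fraction
    exceeds ``threshold``.
    """
    if len(chain) < 2:
        raise ValueError("chain has no jumps")
    steps = np.abs(np.diff(chain.states))
    n_jumps = len(steps)
    n_bad = int(np.sum(steps > 1))
    frac = n_bad / n_jumps
    return LinearityReport(
        n_jumps=n_jumps,
        n_nonadjacent=n_bad,
        fraction_nonadjacent=frac,
        ok=frac <= threshold,
        threshold=threshold,
    )


def check_triplet_coverage(chain: JumpChain, min_count: int = 50) -> dict:
    """Count i -> j -> k passages and warn about under-sampled triplets.

    Mirrors the practical failure mode of equal partitions on rugged
    trajectories: boundary states are visited too rarely to estimate their
    waiting-time distributions.
    """
    s = chain.states
    counts: dict[tuple, int] = {}
    if len(s) >= 3:
        trip = np.stack([s[:-2], s[1:-1], s[2:]], axis=1)
        uniq, cnt = np.unique(trip, axis=0, return_counts=True)
        counts = {tuple(int(v) for v in row): int(c) for row, c in zip(uniq, cnt)}
    sparse = {t: c for t, c in counts.items() if c < min_count}
    if sparse:
        warnings.warn(
            f"{len(sparse)} triplet(s) below the minimum sample count {min_count}: "
            f"{sorted(sparse)[:6]}...; their waiting-time statistics will be excluded",
            UserWarning,
            stacklevel=2,
        )
    return counts
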