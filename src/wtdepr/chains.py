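"""Jump-chain container shared by the CTMC, coarse-graining and estimator layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["JumpChain"]


@dataclass(frozen=True)
class JumpChain:
    """Ordered sequence of (state, dwell time) pairs.

    ``states`` are integer macrostate labels with no immediate repeats and
    ``dwells`` the matching strictly positive dwell times in seconds.  This
    is the common currency of Gillespie output, lumped chains, discretized
    Langevin trajectories and the synthetic semi-Markov generator.
    """

    states: np.ndarray
    dwells: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        dwells = np.asarray(self.dwells, dtype=float)
        if states.shape != dwells.shape or states.ndim != 1:
            raise ValueError("states and dwells must be equal-length 1-D arrays")
        if len(states) == 0:
            raise ValueError("empty chain")
        if np.any(dwells <= 0):
            raise ValueError("dwell times must be strictly positive")
        if len(states) > 1 and np.any(states[1:] == states[:-1]):
            raise ValueError("consecutive states must differ")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "dwells", dwells)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def total_time(self) -> float:
        """Total duration covered by the chain, s."""
        return float(self.dwells.sum())

    @property
    def n_jumps(self) -> int:
        """Number of state-to-state transitions."""
        return len(self.states) - 1

    def slice(self, start: int, stop: int) -> "JumpChain":
        return JumpChain(self.states[start:stop], self.dwells[start:stop], dict(self.meta))

    def to_text(self, path) -> None:
        """Serialize as two-column delimited text (state, dwell_s)."""
        np.savetxt(
            path,
            np.column_stack([self.states.astype(float), self.dwells]),
            delimiter="\t",
            header="state\tdwell_s",
            fmt=["%d", "%.17g"],
        )

    @staticmethod
    def from_text(path) -> "JumpChain":
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        return JumpChain(data[:, 0].astype(np.int64), data[:, 1])
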