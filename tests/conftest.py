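"""Shared fixtures: moderate-length simulations reused across test modules."""

import warnings

import numpy as np
import pytest

from wtdepr import FIG1_PRESET, SimConfig, simulate
from wtdepr.ctmc import default_six_state_spec, gillespie_simulate, lump_trajectory


@pytest.fixture(scope="session")
def driven_traj():
    """Driven hair-bundle run (F_max = 70 pN, S = 1, Teff/T = 1.5)."""
    cfg = SimConfig(dt=0.01, n_steps=1_500_000, burn_in_steps=100_000, seed=1)
    return simulate(FIG1_PRESET, cfg)


@pytest.fixture(scope="session")
def equilibrium_traj():
    """Equilibrium run: no active force, motor noise at bath temperature."""
    params = FIG1_PRESET.replace(F_max=0.0, Teff_over_T=1.0)
    cfg = SimConfig(dt=0.01, n_steps=1_500_000, burn_in_steps=100_000, seed=2)
    return simulate(params, cfg)


@pytest.fixture(scope="session")
def six_state_spec():
    return default_six_state_spec()


@pytest.fixture(scope="session")
def lumped_ctmc_chain(six_state_spec):
    """Lumped (3-state) chain from a 200k-jump Gillespie run."""
    micro = gillespie_simulate(six_state_spec, n_jumps=200_000, seed=3)
    return lump_trajectory(micro, six_state_spec.lump_map)


@pytest.fixture()
def no_coverage_warnings():
    """Silence sparse-triplet coverage warnings in pipeline-level tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def block_stderr(x: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error of the mean of a correlated series via block means."""
    edges = np.linspace(0, len(x), n_blocks + 1, dtype=int)
    means = np.array([x[edges[i] : edges[i + 1]].mean() for i in range(n_blocks)])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
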