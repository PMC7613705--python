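"""Active hair-bundle model: coupled overdamped Langevin equations.

The model describes spontaneous oscillations of a mechanosensory hair
bundle.  The observed coordinate ``X1`` is the bundle tip position; the
hidden coordinate ``X2`` is the centre of mass of the molecular motors.
Both relax in a shared potential ``V(X1, X2)`` built from a gating-spring
term, a pivot-spring term and the free energy of ``N`` two-state
transduction channels; the motors additionally exert a non-conservative
active force ``F_act = F_max (1 - S P0)`` regulated by the channel open
probability ``P0`` (calcium feedback of strength ``S``), and feel thermal
noise at an elevated effective temperature ``T_eff >= T``.

Units throughout: length nm, force pN, energy pN nm, time s (the friction
coefficients are in pN s / nm, so all rates come out per second).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "HairBundleParams",
    "SimConfig",
    "Trajectory",
    "FIG1_PRESET",
    "open_probability",
    "potential_energy",
    "grad_potential",
    "active_force",
    "simulate",
]


@dataclass(frozen=True)
class HairBundleParams:
    """Physical constants of the hair-bundle model.

    Attributes
    ----------
    lambda1, lambda2 : float
        Friction coefficients of the tip and of the motors, pN s / nm.
    k_gs, k_sp : float
        Gating-spring and pivot stiffness, pN / nm.
    D : float
        Gating swing (channel conformational displacement), nm.
    N_channels : int
        Number of transduction channels.
    kBT : float
        Thermal energy of the bath, pN nm.
    Teff_over_T : float
        Effective-to-bath temperature ratio of the motor noise;
        1 at equilibrium, > 1 under active driving.
    deltaG_over_kBT : float
        Open/closed free-energy gap of one channel, in units of kBT.
    F_max : float
        Maximal motor force, pN.
    S : float
        Calcium-feedback strength (dimensionless).
    """

    lambda1: float = 2.8
    lambda2: float = 10.0
    k_gs: float = 0.75
    k_sp: float = 0.6
    D: float = 61.0
    N_channels: int = 50
    kBT: float = 4.0
    Teff_over_T: float = 1.5
    deltaG_over_kBT: float = 10.0
    F_max: float = 70.0
    S: float = 1.0

    def __post_init__(self) -> None:
        positive = {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "k_gs": self.k_gs,
            "k_sp": self.k_sp,
            "kBT": self.kBT,
            "N_channels": self.N_channels,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.Teff_over_T < 1.0:
            raise ValueError("Teff_over_T must be >= 1 (equal to 1 at equilibrium)")
        if self.F_max < 0:
            raise ValueError("F_max must be >= 0")
        if self.S < 0:
            raise ValueError("S must be >= 0")

    @property
    def ln_A(self) -> float:
        """log of the channel gating constant A = exp[(dG + k_gs D^2 / 2N) / kBT]."""
        dG = self.deltaG_over_kBT * self.kBT
        return (dG + self.k_gs * self.D**2 / (2.0 * self.N_channels)) / self.kBT

    def replace(self, **changes) -> "HairBundleParams":
        return dataclasses.replace(self, **changes)


#: Driven reference parameter set (F_max = 70 pN, S = 1, Teff/T = 1.5).
FIG1_PRESET = HairBundleParams()


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for the Euler-Maruyama run.

    ``noise_scale`` multiplies both noise amplitudes; 0 gives the
    deterministic (zero-temperature) flow, used for fixed-point checks.
    """

    dt: float = 0.01
    n_steps: int = 1_000_000
    burn_in_steps: int = 100_000
    seed: int = 0
    x1_init: float = 0.0
    x2_init: float = 0.0
    record_stride: int = 1
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.burn_in_steps >= self.n_steps:
            raise ValueError("burn_in_steps must be smaller than n_steps")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled record of a Langevin run."""

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    params: HairBundleParams
    config: SimConfig

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x1) == len(self.x2)):
            raise ValueError("times, x1, x2 must have equal lengths")

    @property
    def dt_sample(self) -> float:
        """Sampling interval of the record, s."""
        return self.config.dt * self.config.record_stride

    def to_text(self, path) -> None:
        """Write the record as delimited text (time_s, x1_nm, x2_nm)."""
        header = "time_s\tx1_nm\tx2_nm\n# params: " + json.dumps(
            dataclasses.asdict(self.params)
        )
        np.savetxt(
            path,
            np.column_stack([self.times, self.x1, self.x2]),
            delimiter="\t",
            header=header,
            fmt="%.17g",
        )

    @staticmethod
    def from_text(path, params=None, config=None) -> "Trajectory":
        data = np.loadtxt(path, delimiter="\t")
        params = params if params is not None else FIG1_PRESET
        dt = float(data[1, 0] - data[0, 0]) if len(data) > 1 else 1.0
        config = config if config is not None else SimConfig(dt=dt, n_steps=2, burn_in_steps=0)
        return Trajectory(data[:, 0], data[:, 1], data[:, 2], params, config)

    def to_hdf5(self, path) -> None:
        """Lossless binary container with parameter/config metadata as attrs."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("x1", data=self.x1)
            fh.create_dataset("x2", data=self.x2)
            for k, v in dataclasses.asdict(self.params).items():
                fh.attrs[f"params/{k}"] = v
            for k, v in dataclasses.asdict(self.config).items():
                fh.attrs[f"config/{k}"] = v

    @staticmethod
    def from_hdf5(path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            params_kw = {
                k.split("/", 1)[1]: v for k, v in fh.attrs.items() if k.startswith("params/")
            }
            config_kw = {
                k.split("/", 1)[1]: v for k, v in fh.attrs.items() if k.startswith("config/")
            }
            params_kw["N_channels"] = int(params_kw["N_channels"])
            for key in ("n_steps", "burn_in_steps", "seed", "record_stride"):
                config_kw[key] = int(config_kw[key])
            return Trajectory(
                fh["times"][:],
                fh["x1"][:],
                fh["x2"][:],
                HairBundleParams(**params_kw),
                SimConfig(**config_kw),
            )


def _validate_positions(x1, x2) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("positions must be finite")
    return x1, x2


def open_probability(x1, x2, params: HairBundleParams):
    """Channel open probability P0(X1, X2) = 1 / [1 + A exp(-k_gs D dX / N kBT)].

    Evaluated in logistic form ``sigmoid(a - ln A)`` with
    ``a = k_gs D dX / (N kBT)``, which saturates to 0/1 without overflow.
    """
    x1, x2 = _validate_positions(x1, x2)
    a = params.k_gs * params.D * (x1 - x2) / (params.N_channels * params.kBT)
    z = a - params.ln_A
    # stable logistic: exp of a non-positive argument only
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))), np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return out if out.ndim else float(out)


def potential_energy(x1, x2, params: HairBundleParams):
    """Conservative potential V(X1, X2), pN nm.

    V = k_gs dX^2/2 + k_sp X1^2/2 - N kBT ln[exp(k_gs D dX / N kBT) + A],
    with the log-sum-exp term computed stably.
    """
    x1, x2 = _validate_positions(x1, x2)
    dX = x1 - x2
    NkBT = params.N_channels * params.kBT
    a = params.k_gs * params.D * dX / NkBT
    lse = np.logaddexp(a, params.ln_A)
    out = 0.5 * params.k_gs * dX**2 + 0.5 * params.k_sp * x1**2 - NkBT * lse
    return out if out.ndim else float(out)


def grad_potential(x1, x2, params: HairBundleParams):
    """Analytic gradient of the potential: (dV/dX1, dV/dX2), pN.

    dV/dX1 = k_gs (dX - D P0) + k_sp X1 and dV/dX2 = -k_gs (dX - D P0),
    where P0 is the channel open probability.
    """
    x1, x2 = _validate_positions(x1, x2)
    dX = x1 - x2
    p0 = open_probability(x1, x2, params)
    gating = params.k_gs * (dX - params.D * p0)
    g1 = gating + params.k_sp * x1
    g2 = -gating
    if np.ndim(g1) == 0:
        return float(g1), float(g2)
    return np.asarray(g1), np.asarray(g2)


def active_force(x1, x2, params: HairBundleParams):
    """Non-conservative motor force F_act = F_max (1 - S P0(X1, X2)), pN."""
    x1, x2 = _validate_positions(x1, x2)
    out = params.F_max * (1.0 - params.S * open_probability(x1, x2, params))
    return out if np.ndim(out) else float(out)


@njit(cache=True)
def _em_loop(
    x1_0,
    x2_0,
    dt,
    n_steps,
    burn_in,
    stride,
    seed,
    lambda1,
    lambda2,
    k_gs,
    k_sp,
    D,
    N,
    kBT,
    Teff_over_T,
    ln_A,
    F_max,
    S,
    noise_scale,
):  # pragma: no cover - exercised through simulate()
    np.random.seed(seed)
    n_rec = (n_steps - burn_in) // stride
    rec1 = np.empty(n_rec)
    rec2 = np.empty(n_rec)
    amp1 = noise_scale * np.sqrt(2.0 * kBT * dt / lambda1)
    amp2 = noise_scale * np.sqrt(2.0 * kBT * Teff_over_T * dt / lambda2)
    NkBT = N * kBT
    x1 = x1_0
    x2 = x2_0
    idx = 0
    for step in range(n_steps):
        dX = x1 - x2
        z = k_gs * D * dX / NkBT - ln_A
        if z >= 0:
            p0 = 1.0 / (1.0 + np.exp(-z))
        else:
            ez = np.exp(z)
            p0 = ez / (1.0 + ez)
        gating = k_gs * (dX - D * p0)
        f1 = -(gating + k_sp * x1)
        f2 = gating - F_max * (1.0 - S * p0)
        x1 = x1 + dt * f1 / lambda1 + amp1 * np.random.normal()
        x2 = x2 + dt * f2 / lambda2 + amp2 * np.random.normal()
        if abs(x1) > 1.0e4 or abs(x2) > 1.0e4:
            return rec1, rec2, idx, step
        if step >= burn_in and (step - burn_in) % stride == 0:
            rec1[idx] = x1
            rec2[idx] = x2
            idx += 1
    return rec1, rec2, idx, -1


def simulate(params: HairBundleParams, config: SimConfig) -> Trajectory:
    """Integrate the coupled Langevin equations by Euler-Maruyama.

    The tip obeys ``lambda1 dX1 = -dV/dX1 dt + sqrt(2 kBT lambda1) dW1``;
    the motors obey ``lambda2 dX2 = (-dV/dX2 - F_act) dt +
    sqrt(2 kB Teff lambda2) dW2`` with independent Wiener increments.
    Deterministic given ``config.seed``; the burn-in segment is discarded.

    Raises
    ------
    RuntimeError
        If a coordinate exceeds 1e4 nm, indicating a too-large step size.
    """
    rec1, rec2, n_rec, diverged_at = _em_loop(
        config.x1_init,
        config.x2_init,
        config.dt,
        config.n_steps,
        config.burn_in_steps,
        config.record_stride,
        config.seed,
        params.lambda1,
        params.lambda2,
        params.k_gs,
        params.k_sp,
        params.D,
        params.N_channels,
        params.kBT,
        params.Teff_over_T,
        params.ln_A,
        params.F_max,
        params.S,
        config.noise_scale,
    )
    if diverged_at >= 0:
        raise RuntimeError(
            f"trajectory diverged (|x| > 1e4 nm) at step {diverged_at}; "
            f"reduce dt (currently {config.dt} ms)"
        )
    dt_sample = config.dt * config.record_stride
    times = np.arange(n_rec) * dt_sample
    return Trajectory(times, rec1[:n_rec], rec2[:n_rec], params, config)
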