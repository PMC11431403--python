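"""Trajectory integration: deterministic Hamilton dynamics and Langevin
thermostatted dynamics of the donor-acceptor dimer.

The stochastic scheme follows the white-noise discretisation in which each
fixed macro-step of length ``dt`` receives a single Gaussian force per mode,
drawn with zero mean and variance ``2 gamma kBT / dt`` and held frozen across
the internal Runge-Kutta stages.  At ``kBT = 0`` no random numbers are drawn
and the integration is fully deterministic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import _kernels
from .model import DimerParams, SystemState, NORM_TOL

__all__ = [
    "IntegratorConfig",
    "NoiseModel",
    "Trajectory",
    "initial_state",
    "integrate",
    "run_ensemble",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integration settings.

    ``dt`` is the macro-step (default 0.001); ``t_max`` the horizon.  The
    method is the Dormand-Prince Runge-Kutta 5(4) pair run at a fixed step
    (the embedded 4th-order result serves only as an error diagnostic, since
    adaptive stepping would break the Langevin noise variance).  Trajectories
    are sampled every ``sample_stride`` macro-steps; ``None`` picks a stride
    that keeps roughly 2000 samples.  With ``renormalize=False`` (default)
    the electronic norm is monitored and a drift beyond ``norm_tol`` is a
    hard error rather than being silently rescaled away.
    ``strict_transfer_sign`` escalates a sign change of the effective
    transfer integral ``eps_x + k_x u_x`` (an artifact of the linearised
    coupling) from a warning to an error.
    """

    dt: float = 0.001
    t_max: float = 200.0
    method: str = "rk54-fixed"
    renormalize: bool = False
    norm_tol: float = NORM_TOL
    sample_stride: int | None = None
    strict_transfer_sign: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_max < self.dt:
            raise ValueError(f"t_max ({self.t_max}) must be >= dt ({self.dt})")
        if self.method != "rk54-fixed":
            raise ValueError(f"unknown integration method {self.method!r}")

    def resolve_steps(self) -> tuple[int, int]:
        """Number of macro-steps and sampling stride actually used.

        The step count is trimmed to a multiple of the stride so sampled
        times stay uniformly spaced, shortening the horizon by at most
        ``stride * dt``.
        """
        n_steps = int(round(self.t_max / self.dt))
        stride = self.sample_stride
        if stride is None:
            stride = max(1, n_steps // 2000)
        if stride < 1:
            raise ValueError(f"sample_stride must be >= 1, got {stride}")
        n_steps = max(stride, (n_steps // stride) * stride)
        return n_steps, stride


@dataclass(frozen=True)
class NoiseModel:
    """Langevin bath temperature and PRNG seed.

    ``kBT`` is the bath temperature in the model's energy units; ``kBT = 0``
    reproduces the deterministic dynamics exactly (no random draws).  Each
    macro-step consumes one ordered pair (eta_z, eta_x) of Gaussian forces
    with variances ``2 gamma_z kBT / dt`` and ``2 gamma_x kBT / dt``.
    """

    kBT: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kBT < 0:
            raise ValueError(f"kBT must be non-negative, got {self.kBT}")

    def draw_forces(self, n_steps: int, dt: float,
                    params: DimerParams) -> np.ndarray | None:
        """Per-step (eta_z, eta_x) forces, or None when noiseless."""
        if self.kBT == 0.0:
            return None
        rng = np.random.default_rng(self.seed)
        draws = rng.standard_normal((n_steps, 2))
        draws[:, 0] *= math.sqrt(2.0 * params.gamma_z * self.kBT / dt)
        draws[:, 1] *= math.sqrt(2.0 * params.gamma_x * self.kBT / dt)
        return draws


@dataclass
class Trajectory:
    """Sampled time series from one integration.

    ``y`` holds the 8 packed real components per sample (see
    :meth:`SystemState.as_vector`); ``P_D``/``P_A`` are the site occupation
    probabilities and ``energy`` the total dimer + mode energy.  Metadata
    records the run's provenance (parameters, seed, step, diagnostics).
    """

    times: np.ndarray
    y: np.ndarray
    P_D: np.ndarray
    P_A: np.ndarray
    energy: np.ndarray
    params: DimerParams
    dt: float
    kBT: float = 0.0
    seed: int | None = None
    max_norm_drift: float = 0.0
    max_embedded_error: float = 0.0
    transfer_sign_flips: int = 0

    @property
    def states(self) -> list[SystemState]:
        return [SystemState.from_vector(self.y[i], self.times[i])
                for i in range(len(self.times))]

    @property
    def phi_D(self) -> np.ndarray:
        return self.y[:, 0] + 1j * self.y[:, 1]

    @property
    def phi_A(self) -> np.ndarray:
        return self.y[:, 2] + 1j * self.y[:, 3]

    @property
    def u_z(self) -> np.ndarray:
        return self.y[:, 4]

    @property
    def u_x(self) -> np.ndarray:
        return self.y[:, 6]

    def final_state(self) -> SystemState:
        return SystemState.from_vector(self.y[-1], self.times[-1])

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        frame = pd.DataFrame({
            "t": self.times,
            "re_phi_D": self.y[:, 0], "im_phi_D": self.y[:, 1],
            "re_phi_A": self.y[:, 2], "im_phi_A": self.y[:, 3],
            "P_D": self.P_D, "P_A": self.P_A,
            "u_z": self.y[:, 4], "u_x": self.y[:, 6],
            "p_z": self.y[:, 5], "p_x": self.y[:, 7],
            "energy": self.energy,
        })
        frame.to_csv(path_or_buf, index=False)

    def metadata(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "dt": self.dt,
            "kBT": self.kBT,
            "seed": self.seed,
            "n_samples": int(len(self.times)),
            "t_final": float(self.times[-1]),
            "max_norm_drift": self.max_norm_drift,
            "max_embedded_error": self.max_embedded_error,
            "transfer_sign_flips": self.transfer_sign_flips,
        }

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def initial_state(params: DimerParams,
                  electron_on: Literal["donor", "acceptor"] = "donor") -> SystemState:
    """Equilibrium initial condition with the electron fully localised.

    The modes start at the stationary point they relax to for the chosen
    electronic state:

        u_x = -(k_x / Omega_x^2) * 2 Re(phi_D* phi_A)   (= 0 when localised)
        u_z = -(k_z / Omega_z^2) * (|phi_A|^2 - |phi_D|^2)

    with zero velocities and zero electronic phase.  For a donor-localised
    electron this is an exact stationary point of the deterministic flow.
    """
    if electron_on == "donor":
        phi_D, phi_A = 1.0 + 0.0j, 0.0 + 0.0j
    elif electron_on == "acceptor":
        phi_D, phi_A = 0.0 + 0.0j, 1.0 + 0.0j
    else:
        raise ValueError(f"electron_on must be 'donor' or 'acceptor', got {electron_on!r}")
    charge = abs(phi_A) ** 2 - abs(phi_D) ** 2
    bond = 2.0 * (phi_D.conjugate() * phi_A).real
    return SystemState(
        phi_D=phi_D, phi_A=phi_A,
        u_z=-(params.k_z / params.Omega_z ** 2) * charge + 0.0,
        u_x=-(params.k_x / params.Omega_x ** 2) * bond + 0.0,
        p_z=0.0, p_x=0.0, t=0.0,
    )


def _energy_series(y: np.ndarray, params: DimerParams) -> np.ndarray:
    pD = y[:, 0] ** 2 + y[:, 1] ** 2
    pA = y[:, 2] ** 2 + y[:, 3] ** 2
    bond = 2.0 * (y[:, 0] * y[:, 2] + y[:, 1] * y[:, 3])
    return (params.E_D * pD + params.E_A * pA
            + params.k_z * y[:, 4] * (pA - pD)
            + (params.eps_x + params.k_x * y[:, 6]) * bond
            + 0.5 * y[:, 5] ** 2 + 0.5 * params.Omega_z ** 2 * y[:, 4] ** 2
            + 0.5 * y[:, 7] ** 2 + 0.5 * params.Omega_x ** 2 * y[:, 6] ** 2)


def integrate(state0: SystemState, params: DimerParams,
              noise: NoiseModel | None = None,
              config: IntegratorConfig | None = None) -> Trajectory:
    """Integrate the dimer equations of motion from ``state0``.

    With ``noise=None`` (or ``kBT=0``) the run is deterministic; otherwise
    Langevin forces with the fluctuation-dissipation variance
    ``2 gamma kBT / dt`` are applied per macro-step.  Runs with identical
    seeds are bitwise reproducible.
    """
    noise = noise or NoiseModel(kBT=0.0)
    config = config or IntegratorConfig()
    state0.validate(config.norm_tol)

    n_steps, stride = config.resolve_steps()
    forces = noise.draw_forces(n_steps, config.dt, params)
    use_noise = forces is not None
    if forces is None:
        forces = np.zeros((1, 2))

    out = np.empty((n_steps // stride + 1, 8))
    status, bad_step, max_drift, max_err, sign_flips = _kernels.integrate_fixed_rk54(
        state0.as_vector(), n_steps, config.dt,
        params.E_D, params.E_A, params.k_z, params.k_x, params.eps_x,
        params.Omega_z ** 2, params.Omega_x ** 2,
        params.gamma_z, params.gamma_x,
        forces, use_noise, stride, out,
        config.renormalize, config.norm_tol,
    )
    t_bad = state0.t + bad_step * config.dt
    if status == _kernels.STATUS_NORM_DRIFT:
        raise RuntimeError(
            f"electronic norm drift {max_drift:.3e} exceeded tolerance "
            f"{config.norm_tol:.1e} at t = {t_bad:.6g}"
        )
    if status == _kernels.STATUS_NON_FINITE:
        raise RuntimeError(f"integration diverged (non-finite state) at t = {t_bad:.6g}")

    if sign_flips > 0:
        msg = (f"effective transfer integral eps_x + k_x*u_x changed sign on "
               f"{sign_flips} step(s): the linearised coupling is outside its "
               f"domain of validity")
        if config.strict_transfer_sign:
            raise RuntimeError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    times = state0.t + config.dt * stride * np.arange(out.shape[0])
    return Trajectory(
        times=times, y=out,
        P_D=out[:, 0] ** 2 + out[:, 1] ** 2,
        P_A=out[:, 2] ** 2 + out[:, 3] ** 2,
        energy=_energy_series(out, params),
        params=params, dt=config.dt, kBT=noise.kBT,
        seed=noise.seed if use_noise else None,
        max_norm_drift=max_drift, max_embedded_error=max_err,
        transfer_sign_flips=sign_flips,
    )


def run_ensemble(params: DimerParams, kBT: float, n_runs: int, base_seed: int,
                 config: IntegratorConfig | None = None,
                 electron_on: Literal["donor", "acceptor"] = "donor") -> list[Trajectory]:
    """Integrate ``n_runs`` independently seeded Langevin trajectories.

    Member ``i`` uses seed ``base_seed + i``; all members share the same
    initial condition, parameters and time grid.  Any member failure aborts
    the whole ensemble with the offending seed in the error message.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    config = config or IntegratorConfig()
    state0 = initial_state(params, electron_on)
    members: list[Trajectory] = []
    for i in range(n_runs):
        seed = base_seed + i
        try:
            members.append(integrate(state0, params,
                                     NoiseModel(kBT=kBT, seed=seed), config))
        except Exception as exc:
            raise RuntimeError(f"ensemble member with seed {seed} failed: {exc}") from exc
    return members
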