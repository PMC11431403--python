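"""Donor-acceptor dimer model: parameters, states and the coupled equations of motion.

The model describes an electron (or any two-state quantum excitation) shared
between a donor orbital ``|D>`` and an acceptor orbital ``|A>``, with complex
amplitudes ``phi_D``, ``phi_A``.  The electron is linearly coupled to two
classical vibrational coordinates of its environment:

* ``u_z`` -- the *antisymmetric* (ionic) mode, driven by the charge imbalance
  ``|phi_A|^2 - |phi_D|^2``; it shifts the effective on-site energies.
* ``u_x`` -- the *symmetric* (covalent) mode, driven by the bond order
  ``2 Re(phi_D* phi_A)``; it modulates the transfer integral
  ``eps_x + k_x u_x``.

Working units are hbar = 1 (time measured in 1/hbar, energies in hbar) and
unit oscillator masses, so mode momenta coincide with velocities.

Targeted energy transfer (TET) -- resonant, barrier-free transfer -- occurs
in the neighbourhood of the parameter degeneracy

    E_D = E_A,    k_z^2/Omega_z^2 = k_x^2/Omega_x^2,    eps_x = 0,

which :func:`check_tet` tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "DimerParams",
    "SystemState",
    "StateDerivative",
    "TETResidual",
    "total_energy",
    "electronic_matrix",
    "equations_of_motion",
    "check_tet",
]

#: default tolerance on the squared-norm constraint |phi_D|^2 + |phi_A|^2 = 1
NORM_TOL = 1e-6

#: default tolerance for the exact TET degeneracy conditions
TET_TOL = 1e-9


@dataclass(frozen=True)
class DimerParams:
    """Model constants of the dimer Hamiltonian, in hbar = 1 units.

    Parameters
    ----------
    E_D, E_A
        On-site electronic energies of the donor and acceptor.
    k_z
        Coupling of the antisymmetric (ionic) mode to the charge imbalance.
    k_x
        Coupling of the symmetric (covalent) mode to the bond order.
    eps_x
        Bare transfer integral (orbital overlap at the reference geometry).
    Omega_z, Omega_x
        Harmonic frequencies of the two modes; must be positive.
    gamma_z, gamma_x
        Langevin bath dampings of the two modes; must be non-negative.
    """

    E_D: float = 0.0
    E_A: float = 0.0
    k_z: float = 1.0
    k_x: float = 1.0
    eps_x: float = 0.0
    Omega_z: float = 1.0
    Omega_x: float = 1.0
    gamma_z: float = 0.0
    gamma_x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E_D", "E_A", "k_z", "k_x", "eps_x",
                     "Omega_z", "Omega_x", "gamma_z", "gamma_x"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"DimerParams.{name} must be finite, got {value!r}")
            object.__setattr__(self, name, float(value))
        if self.Omega_z <= 0 or self.Omega_x <= 0:
            raise ValueError(
                f"mode frequencies must be positive: Omega_z={self.Omega_z}, "
                f"Omega_x={self.Omega_x}"
            )
        if self.gamma_z < 0 or self.gamma_x < 0:
            raise ValueError(
                f"dampings must be non-negative: gamma_z={self.gamma_z}, "
                f"gamma_x={self.gamma_x}"
            )

    def replace(self, **changes) -> "DimerParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "DimerParams":
        """Build from a mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown DimerParams field(s): {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "DimerParams":
        return cls.from_dict(json.loads(text))


@dataclass
class SystemState:
    """Instantaneous dynamical state of the dimer.

    ``phi_D`` and ``phi_A`` are the complex electronic amplitudes; the squared
    norm ``|phi_D|^2 + |phi_A|^2`` must equal 1 within ``NORM_TOL``.  ``u_z``,
    ``u_x`` are the mode coordinates and ``p_z``, ``p_x`` their velocities
    (unit masses).  ``t`` is the time in 1/hbar units.
    """

    phi_D: complex
    phi_A: complex
    u_z: float = 0.0
    u_x: float = 0.0
    p_z: float = 0.0
    p_x: float = 0.0
    t: float = 0.0

    @property
    def norm2(self) -> float:
        """Total electronic occupation |phi_D|^2 + |phi_A|^2."""
        return abs(self.phi_D) ** 2 + abs(self.phi_A) ** 2

    @property
    def P_D(self) -> float:
        return abs(self.phi_D) ** 2

    @property
    def P_A(self) -> float:
        return abs(self.phi_A) ** 2

    def validate(self, norm_tol: float = NORM_TOL) -> None:
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite system state: {self}")
        if abs(self.norm2 - 1.0) > norm_tol:
            raise ValueError(
                f"electronic norm violated: |phi_D|^2+|phi_A|^2 = {self.norm2!r} "
                f"(tolerance {norm_tol})"
            )

    def as_vector(self) -> np.ndarray:
        """Pack into the 8 real components used by the integrator.

        Order: Re phi_D, Im phi_D, Re phi_A, Im phi_A, u_z, p_z, u_x, p_x.
        """
        return np.array(
            [self.phi_D.real, self.phi_D.imag,
             self.phi_A.real, self.phi_A.imag,
             self.u_z, self.p_z, self.u_x, self.p_x],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float = 0.0) -> "SystemState":
        return cls(
            phi_D=complex(y[0], y[1]),
            phi_A=complex(y[2], y[3]),
            u_z=float(y[4]), p_z=float(y[5]),
            u_x=float(y[6]), p_x=float(y[7]),
            t=float(t),
        )


class StateDerivative(NamedTuple):
    """Time derivative of a :class:`SystemState` (same field layout, no t)."""

    phi_D: complex
    phi_A: complex
    u_z: float
    u_x: float
    p_z: float
    p_x: float


@dataclass(frozen=True)
class TETResidual:
    """Residuals of the three TET degeneracy conditions.

    ``d_energy = E_A - E_D`` (resonance of the on-site levels),
    ``d_balance = k_z^2/Omega_z^2 - k_x^2/Omega_x^2`` (ionic/covalent
    balance), ``d_transfer = eps_x`` (vanishing bare transfer integral).
    ``is_tet`` holds iff all three magnitudes are within the tolerance used
    by :func:`check_tet`.
    """

    d_energy: float
    d_balance: float
    d_transfer: float
    is_tet: bool

    def max_abs(self) -> float:
        return max(abs(self.d_energy), abs(self.d_balance), abs(self.d_transfer))


def total_energy(state: SystemState, params: DimerParams,
                 norm_tol: float = NORM_TOL) -> float:
    """Total energy of the dimer + modes (baths excluded).

    H = E_D |phi_D|^2 + E_A |phi_A|^2
        + k_z u_z (|phi_A|^2 - |phi_D|^2)
        + (eps_x + k_x u_x) * 2 Re(phi_D* phi_A)
        + p_z^2/2 + Omega_z^2 u_z^2/2 + p_x^2/2 + Omega_x^2 u_x^2/2
    """
    state.validate(norm_tol)
    pD = abs(state.phi_D) ** 2
    pA = abs(state.phi_A) ** 2
    bond = 2.0 * (state.phi_D.conjugate() * state.phi_A).real
    return (
        params.E_D * pD
        + params.E_A * pA
        + params.k_z * state.u_z * (pA - pD)
        + (params.eps_x + params.k_x * state.u_x) * bond
        + 0.5 * state.p_z ** 2 + 0.5 * params.Omega_z ** 2 * state.u_z ** 2
        + 0.5 * state.p_x ** 2 + 0.5 * params.Omega_x ** 2 * state.u_x ** 2
    )


def electronic_matrix(u_x: float, u_z: float, params: DimerParams) -> np.ndarray:
    """Electronic 2x2 Hamiltonian at frozen mode coordinates.

    Rows/columns are ordered (donor, acceptor)::

        [[E_D - k_z u_z,  eps_x + k_x u_x],
         [eps_x + k_x u_x, E_A + k_z u_z]]

    The matrix is real symmetric by construction; its eigenvalues are the two
    adiabatic electronic levels at ``(u_x, u_z)``.
    """
    if not (math.isfinite(u_x) and math.isfinite(u_z)):
        raise ValueError(f"non-finite coordinates: u_x={u_x!r}, u_z={u_z!r}")
    g = params.eps_x + params.k_x * u_x
    return np.array(
        [[params.E_D - params.k_z * u_z, g],
         [g, params.E_A + params.k_z * u_z]],
        dtype=float,
    )


def equations_of_motion(state: SystemState, params: DimerParams,
                        noise_z: float = 0.0, noise_x: float = 0.0) -> StateDerivative:
    """Right-hand side of the coupled electron-mode (Langevin) equations.

    i phi_D' = (E_D - k_z u_z) phi_D + (eps_x + k_x u_x) phi_A
    i phi_A' = (E_A + k_z u_z) phi_A + (eps_x + k_x u_x) phi_D
    u_z''    = -gamma_z u_z' - Omega_z^2 u_z - k_z (|phi_A|^2 - |phi_D|^2) + eta_z
    u_x''    = -gamma_x u_x' - Omega_x^2 u_x - k_x 2 Re(phi_D* phi_A) + eta_x

    ``noise_z`` / ``noise_x`` are the instantaneous Langevin forces (0 for
    deterministic evolution).  The electronic part is generated by the
    Hermitian matrix of :func:`electronic_matrix`, so the squared norm is an
    exact invariant of the flow.
    """
    vec = state.as_vector()
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite system state: {state}")
    if not (math.isfinite(noise_z) and math.isfinite(noise_x)):
        raise ValueError(f"non-finite noise forces: {noise_z!r}, {noise_x!r}")
    g = params.eps_x + params.k_x * state.u_x
    dphi_D = -1j * ((params.E_D - params.k_z * state.u_z) * state.phi_D
                    + g * state.phi_A)
    dphi_A = -1j * ((params.E_A + params.k_z * state.u_z) * state.phi_A
                    + g * state.phi_D)
    charge = abs(state.phi_A) ** 2 - abs(state.phi_D) ** 2
    bond = 2.0 * (state.phi_D.conjugate() * state.phi_A).real
    dp_z = (-params.gamma_z * state.p_z - params.Omega_z ** 2 * state.u_z
            - params.k_z * charge + noise_z)
    dp_x = (-params.gamma_x * state.p_x - params.Omega_x ** 2 * state.u_x
            - params.k_x * bond + noise_x)
    return StateDerivative(phi_D=dphi_D, phi_A=dphi_A,
                           u_z=state.p_z, u_x=state.p_x,
                           p_z=dp_z, p_x=dp_x)


def check_tet(params: DimerParams, tol: float = TET_TOL) -> TETResidual:
    """Evaluate the three TET degeneracy residuals at the given tolerance."""
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    d_energy = params.E_A - params.E_D
    d_balance = (params.k_z ** 2 / params.Omega_z ** 2
                 - params.k_x ** 2 / params.Omega_x ** 2)
    d_transfer = params.eps_x
    is_tet = (abs(d_energy) <= tol and abs(d_balance) <= tol
              and abs(d_transfer) <= tol)
    return TETResidual(d_energy=d_energy, d_balance=d_balance,
                       d_transfer=d_transfer, is_tet=is_tet)
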