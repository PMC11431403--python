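"""Potential-energy-surface analysis: adiabatic surfaces, conical intersection,
anti-adiabatic reduced potential and Marcus/TET regime classification.

At frozen mode coordinates ``(u_x, u_z)`` the two adiabatic surfaces are the
harmonic mode energy plus the eigenvalues of the electronic 2x2 matrix:

    V_pm(u_x, u_z) = Omega_z^2 u_z^2/2 + Omega_x^2 u_x^2/2 + (E_D+E_A)/2
                     -/+ sqrt( ((E_D-E_A)/2 - k_z u_z)^2 + (eps_x + k_x u_x)^2 )

They touch at a single conical point ``u_x* = -eps_x/k_x``,
``u_z* = (E_D-E_A)/(2 k_z)`` where both square-root terms vanish.

In the anti-adiabatic (fast-mode) limit the modes follow the electron
instantaneously and the system reduces to a nonlinear dimer in the acceptor
occupation ``rho = |phi_A|^2`` and relative phase ``Delta = alpha_A -
alpha_D``.  Minimising over the phase yields the reduced potential ``F(rho)``
whose shape distinguishes targeted energy transfer (F flat: a degenerate
groove connecting donor and acceptor) from Marcus-type activated transfer
(double well with a barrier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .model import DimerParams, TET_TOL, check_tet

__all__ = [
    "PESGrid",
    "ConicalPoint",
    "ReducedState",
    "adiabatic_surfaces",
    "conical_point",
    "reduced_potential_F",
    "antiadiabatic_energy",
    "classify_regime",
    "reaction_path",
]

RegimeLabel = Literal["tet", "near_tet", "marcus_normal", "marcus_inverted", "away"]

#: default per-residual windows for the "near TET" label: the on-site detuning
#: E_A - E_D may be as large as 1 while the ionic/covalent balance and the
#: bare transfer integral must stay nearly exact.
NEAR_TET_TOL = {"d_energy": 1.0, "d_balance": 0.05, "d_transfer": 0.05}

#: ionic/covalent imbalance beyond which parameters are labelled "away"
#: (far outside both the TET neighbourhood and a clean two-parabola picture).
AWAY_BALANCE_THRESHOLD = 5.0


@dataclass(frozen=True)
class ConicalPoint:
    """Location and energy of the conical intersection of the two surfaces."""

    ux_star: float
    uz_star: float
    energy: float
    gap: float


@dataclass(frozen=True)
class ReducedState:
    """Anti-adiabatic electronic state: occupation rho = |phi_A|^2 in [0, 1]
    and relative phase alpha_A - alpha_D in (-pi, pi]."""

    rho: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho!r}")


@dataclass
class PESGrid:
    """Lower/upper adiabatic surfaces sampled on a rectangular (u_x, u_z) grid.

    ``lower[i, j]`` and ``upper[i, j]`` are the surface energies at
    ``(ux_axis[j], uz_axis[i])`` (row index runs over u_z, matching the
    meshgrid convention).
    """

    ux_axis: np.ndarray
    uz_axis: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    params: DimerParams

    def gap(self) -> np.ndarray:
        return self.upper - self.lower

    def to_csv(self, path_or_buf) -> None:
        """Write the grid as delimited text with columns ux, uz, lower, upper."""
        import pandas as pd

        UX, UZ = np.meshgrid(self.ux_axis, self.uz_axis)
        frame = pd.DataFrame({
            "ux": UX.ravel(), "uz": UZ.ravel(),
            "lower": self.lower.ravel(), "upper": self.upper.ravel(),
        })
        frame.to_csv(path_or_buf, index=False)


def _splitting(ux, uz, params: DimerParams):
    """Half-gap sqrt term of the adiabatic surfaces (vectorised)."""
    return np.sqrt(((params.E_D - params.E_A) / 2.0 - params.k_z * np.asarray(uz)) ** 2
                   + (params.eps_x + params.k_x * np.asarray(ux)) ** 2)


def adiabatic_surfaces(ux_axis: Sequence[float], uz_axis: Sequence[float],
                       params: DimerParams) -> PESGrid:
    """Evaluate both adiabatic surfaces on the rectangular grid.

    Axes must be strictly increasing with at least two points each.  The
    closed form (harmonic offset plus electronic eigenvalues) is used; it
    agrees with an explicit eigendecomposition of the electronic matrix to
    machine precision.
    """
    ux = np.asarray(ux_axis, dtype=float)
    uz = np.asarray(uz_axis, dtype=float)
    for name, axis in (("ux_axis", ux), ("uz_axis", uz)):
        if axis.ndim != 1 or axis.size < 2:
            raise ValueError(f"{name} must be 1-D with at least 2 points")
        if not np.all(np.diff(axis) > 0):
            raise ValueError(f"{name} must be strictly increasing")
    UX, UZ = np.meshgrid(ux, uz)
    harmonic = 0.5 * params.Omega_z ** 2 * UZ ** 2 + 0.5 * params.Omega_x ** 2 * UX ** 2
    mean = 0.5 * (params.E_D + params.E_A)
    split = _splitting(UX, UZ, params)
    return PESGrid(ux_axis=ux, uz_axis=uz,
                   lower=harmonic + mean - split,
                   upper=harmonic + mean + split,
                   params=params)


def conical_point(params: DimerParams) -> ConicalPoint:
    """Locate the conical intersection of the two adiabatic surfaces.

    Both terms under the square root vanish simultaneously only at
    ``u_x* = -eps_x/k_x``, ``u_z* = (E_D - E_A)/(2 k_z)``; the point is
    isolated iff both couplings are nonzero.
    """
    if params.k_z == 0 or params.k_x == 0:
        raise ValueError(
            "no isolated conical point: requires k_z != 0 and k_x != 0 "
            f"(got k_z={params.k_z}, k_x={params.k_x})"
        )
    ux_star = -params.eps_x / params.k_x
    uz_star = (params.E_D - params.E_A) / (2.0 * params.k_z)
    harmonic = (0.5 * params.Omega_z ** 2 * uz_star ** 2
                + 0.5 * params.Omega_x ** 2 * ux_star ** 2)
    mean = 0.5 * (params.E_D + params.E_A)
    gap = 2.0 * float(_splitting(ux_star, uz_star, params))
    return ConicalPoint(ux_star=ux_star, uz_star=uz_star,
                        energy=harmonic + mean, gap=gap)


def antiadiabatic_energy(state: ReducedState, params: DimerParams) -> float:
    """Anti-adiabatic dimer energy H_aa(rho, Delta).

    With ``phi_A = sqrt(rho) e^{i alpha_A}``, ``phi_D = sqrt(1-rho)
    e^{i alpha_D}`` and the modes relaxed to their instantaneous equilibria::

        H_aa = -k_z^2/(2 Omega_z^2) (2 rho - 1)^2
               - 2 k_x^2/Omega_x^2 rho (1-rho) cos^2 Delta
               + E_D (1-rho) + E_A rho
               + 2 eps_x sqrt(rho (1-rho)) cos Delta
    """
    rho, delta = state.rho, state.phase
    amp = math.sqrt(rho * (1.0 - rho))
    return (
        -0.5 * params.k_z ** 2 / params.Omega_z ** 2 * (2.0 * rho - 1.0) ** 2
        - 2.0 * params.k_x ** 2 / params.Omega_x ** 2 * rho * (1.0 - rho)
        * math.cos(delta) ** 2
        + params.E_D * (1.0 - rho) + params.E_A * rho
        + 2.0 * params.eps_x * amp * math.cos(delta)
    )


def reduced_potential_F(rho, params: DimerParams):
    """Phase-minimised anti-adiabatic potential F(rho).

    The minimising phase is Delta = 0 for eps_x < 0 and Delta = pi for
    eps_x > 0 (either for eps_x = 0), collapsing the transfer term to
    ``-2 |eps_x| sqrt(rho (1-rho))``::

        F(rho) = -k_z^2/(2 Omega_z^2) (2 rho - 1)^2
                 - 2 k_x^2/Omega_x^2 rho (1-rho)
                 + E_D (1-rho) + E_A rho - 2 |eps_x| sqrt(rho (1-rho))

    Under the TET degeneracy conditions every rho-dependent term cancels and
    F is constant: the donor and acceptor are connected by a flat groove.
    Accepts a scalar or an array of occupations in [0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0.0) or np.any(rho > 1.0):
        raise ValueError("rho must lie in [0, 1]")
    value = (
        -0.5 * params.k_z ** 2 / params.Omega_z ** 2 * (2.0 * rho - 1.0) ** 2
        - 2.0 * params.k_x ** 2 / params.Omega_x ** 2 * rho * (1.0 - rho)
        + params.E_D * (1.0 - rho) + params.E_A * rho
        - 2.0 * abs(params.eps_x) * np.sqrt(rho * (1.0 - rho))
    )
    return value if value.ndim else float(value)


def _diabatic_crossing_between_minima(params: DimerParams) -> bool:
    """Whether the diabatic parabolas cross between their minima (u_x = 0 cut).

    V_D(u_z) = Omega_z^2 u_z^2/2 + E_D - k_z u_z  (minimum at +k_z/Omega_z^2)
    V_A(u_z) = Omega_z^2 u_z^2/2 + E_A + k_z u_z  (minimum at -k_z/Omega_z^2)

    cross at u_z = (E_D - E_A)/(2 k_z).  A crossing inside the inter-minimum
    interval is the Marcus normal regime; outside, the inverted regime.
    """
    uz_cross = (params.E_D - params.E_A) / (2.0 * params.k_z)
    uz_half_span = abs(params.k_z) / params.Omega_z ** 2
    return abs(uz_cross) < uz_half_span


def classify_regime(params: DimerParams, tol: float = TET_TOL,
                    near_tol: dict | None = None,
                    away_balance: float = AWAY_BALANCE_THRESHOLD) -> RegimeLabel:
    """Classify the parameter set by the shape of its transfer landscape.

    Order of tests:

    1. ``tet`` -- all three degeneracy residuals within ``tol``.
    2. ``near_tet`` -- residuals within the looser per-residual windows
       ``near_tol`` (defaults to :data:`NEAR_TET_TOL`).
    3. ``away`` -- ionic/covalent imbalance ``|d_balance|`` at or beyond
       ``away_balance``: the landscape is dominated by one interaction and
       sits far from both the TET neighbourhood and the balanced two-parabola
       construction.
    4. Otherwise the concavity of ``F(rho)`` decides whether a barrier can
       form: an ionic-dominated landscape (``k_z^2/Omega_z^2 >
       k_x^2/Omega_x^2``, concave quadratic part of F) is activated
       Marcus-type transfer, discriminated into ``marcus_normal`` (diabatic
       parabolas cross between their minima, i.e. driving force below the
       reorganisation energy) and ``marcus_inverted`` (crossing outside);
       a covalent-dominated landscape (convex F: a single hybridised well,
       no reaction barrier) is labelled ``away``.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    residual = check_tet(params, tol)
    if residual.is_tet:
        return "tet"
    windows = dict(NEAR_TET_TOL)
    if near_tol:
        windows.update(near_tol)
    if (abs(residual.d_energy) <= windows["d_energy"]
            and abs(residual.d_balance) <= windows["d_balance"]
            and abs(residual.d_transfer) <= windows["d_transfer"]):
        return "near_tet"
    if abs(residual.d_balance) >= away_balance:
        return "away"
    # quadratic part of F(rho) is 2 (kx^2/Ox^2 - kz^2/Oz^2) (rho^2 - rho):
    # concave (d_balance > 0) is the barrier-forming, ionic-dominated case
    if residual.d_balance > 0:
        if _diabatic_crossing_between_minima(params):
            return "marcus_normal"
        return "marcus_inverted"
    return "away"


def _local_minima(values: np.ndarray) -> list[int]:
    """Indices of strict local minima of a sampled curve, endpoints included."""
    idx = []
    n = len(values)
    for i in range(n):
        left_ok = i == 0 or values[i] < values[i - 1]
        right_ok = i == n - 1 or values[i] < values[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return idx


def reaction_path(params: DimerParams, radius: float,
                  n_angles: int = 360) -> np.ndarray:
    """Angular profile of both surfaces on a circle around the conical point.

    The circle of the given radius is drawn in the frequency-scaled plane
    ``(Omega_x u_x, Omega_z u_z)`` centred at the conical point; under pure
    TET conditions the lower surface is flat along it (the degenerate
    reaction path) and the gap to the upper surface is independent of the
    rotation angle.

    Returns an array of shape ``(n_angles, 3)`` with columns
    (angle alpha in radians, lower energy, upper energy).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    point = conical_point(params)
    alpha = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    ux = point.ux_star + radius * np.cos(alpha) / params.Omega_x
    uz = point.uz_star + radius * np.sin(alpha) / params.Omega_z
    harmonic = 0.5 * params.Omega_z ** 2 * uz ** 2 + 0.5 * params.Omega_x ** 2 * ux ** 2
    mean = 0.5 * (params.E_D + params.E_A)
    split = _splitting(ux, uz, params)
    return np.column_stack([alpha, harmonic + mean - split, harmonic + mean + split])


def pes_summary(params: DimerParams, tol: float = TET_TOL) -> dict:
    """JSON-ready summary: conical point, TET residuals and regime label."""
    point = conical_point(params)
    residual = check_tet(params, tol)
    return {
        "conical_point": {"ux": point.ux_star, "uz": point.uz_star,
                          "energy": point.energy, "gap": point.gap},
        "tet_residuals": {"d_energy": residual.d_energy,
                          "d_balance": residual.d_balance,
                          "d_transfer": residual.d_transfer,
                          "is_tet": residual.is_tet},
        "regime": classify_regime(params, tol),
        "params": params.to_dict(),
    }
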