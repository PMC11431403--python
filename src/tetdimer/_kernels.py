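"""Compiled fixed-step integrator core.

The state is packed into 8 reals: (Re phi_D, Im phi_D, Re phi_A, Im phi_A,
u_z, p_z, u_x, p_x).  The stepper is the Dormand-Prince 5(4) pair run at a
fixed step: adaptive control would break the per-step Langevin noise scaling,
so the embedded 4th-order solution is used only as an accuracy diagnostic.
The Langevin forces (eta_z, eta_x) are frozen over the whole macro-step,
i.e. held constant across the internal stages.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 5(4) Butcher tableau (fixed step).
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
# 5th-order weights (propagated solution)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
# 4th-order embedded weights (error estimate only)
_E1, _E3, _E4, _E5, _E6, _E7 = (5179.0 / 57600.0, 7571.0 / 16695.0,
                                393.0 / 640.0, -92097.0 / 339200.0,
                                187.0 / 2100.0, 1.0 / 40.0)

STATUS_OK = 0
STATUS_NORM_DRIFT = 1
STATUS_NON_FINITE = 2


@njit(cache=False)
def _deriv(y, dy, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x):
    """Right-hand side of the coupled electron-mode Langevin equations."""
    rD, iD, rA, iA = y[0], y[1], y[2], y[3]
    uz, pz, ux, px = y[4], y[5], y[6], y[7]
    hD = E_D - k_z * uz          # effective donor level
    hA = E_A + k_z * uz          # effective acceptor level
    g = eps_x + k_x * ux         # effective transfer integral
    # i phi' = h phi  =>  Re phi' = h Im phi ..., Im phi' = -h Re phi ...
    dy[0] = hD * iD + g * iA
    dy[1] = -(hD * rD + g * rA)
    dy[2] = hA * iA + g * iD
    dy[3] = -(hA * rA + g * rD)
    charge = (rA * rA + iA * iA) - (rD * rD + iD * iD)
    bond = 2.0 * (rD * rA + iD * iA)
    dy[4] = pz
    dy[5] = -g_z * pz - Oz2 * uz - k_z * charge + eta_z
    dy[6] = px
    dy[7] = -g_x * px - Ox2 * ux - k_x * bond + eta_x


@njit(cache=False)
def integrate_fixed_rk54(y0, n_steps, dt,
                         E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x,
                         noise, use_noise, stride, out,
                         renormalize, norm_tol):
    """Advance n_steps macro-steps, sampling every `stride` steps into `out`.

    `noise` has shape (n_steps, 2) with per-step (eta_z, eta_x) forces when
    `use_noise` is true; otherwise it is ignored.  `out` must have shape
    (n_steps // stride + 1, 8).

    Returns (status, bad_step, max_norm_drift, max_embedded_error,
    transfer_sign_flips).
    """
    y = y0.copy()
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    k5 = np.empty(8); k6 = np.empty(8); k7 = np.empty(8)
    ytmp = np.empty(8)
    out[0, :] = y
    max_drift = 0.0
    max_err = 0.0
    sign_flips = 0
    eps_sign = 0.0
    if eps_x > 0.0:
        eps_sign = 1.0
    elif eps_x < 0.0:
        eps_sign = -1.0

    for step in range(n_steps):
        eta_z = 0.0
        eta_x = 0.0
        if use_noise:
            eta_z = noise[step, 0]
            eta_x = noise[step, 1]

        _deriv(y, k1, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)
        for i in range(8):
            ytmp[i] = y[i] + dt * _A21 * k1[i]
        _deriv(ytmp, k2, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)
        for i in range(8):
            ytmp[i] = y[i] + dt * (_A31 * k1[i] + _A32 * k2[i])
        _deriv(ytmp, k3, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)
        for i in range(8):
            ytmp[i] = y[i] + dt * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _deriv(ytmp, k4, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)
        for i in range(8):
            ytmp[i] = y[i] + dt * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i]
                                   + _A54 * k4[i])
        _deriv(ytmp, k5, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)
        for i in range(8):
            ytmp[i] = y[i] + dt * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                                   + _A64 * k4[i] + _A65 * k5[i])
        _deriv(ytmp, k6, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)
        for i in range(8):
            ytmp[i] = y[i] + dt * (_B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                                   + _B5 * k5[i] + _B6 * k6[i])
        _deriv(ytmp, k7, E_D, E_A, k_z, k_x, eps_x, Oz2, Ox2, g_z, g_x, eta_z, eta_x)

        # embedded 4th-order estimate: accuracy diagnostic only
        err = 0.0
        for i in range(8):
            y4 = y[i] + dt * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                              + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i])
            d = ytmp[i] - y4
            if d < 0.0:
                d = -d
            if d > err:
                err = d
        if err > max_err:
            max_err = err

        for i in range(8):
            y[i] = ytmp[i]
        if not np.isfinite(y[0] + y[1] + y[2] + y[3] + y[4] + y[5] + y[6] + y[7]):
            return STATUS_NON_FINITE, step + 1, max_drift, max_err, sign_flips

        nrm = y[0] * y[0] + y[1] * y[1] + y[2] * y[2] + y[3] * y[3]
        drift = nrm - 1.0
        if drift < 0.0:
            drift = -drift
        if renormalize:
            scale = 1.0 / np.sqrt(nrm)
            for i in range(4):
                y[i] *= scale
        elif drift > norm_tol:
            return STATUS_NORM_DRIFT, step + 1, drift, max_err, sign_flips
        if drift > max_drift:
            max_drift = drift

        if eps_sign != 0.0 and eps_sign * (eps_x + k_x * y[6]) < 0.0:
            sign_flips += 1

        if (step + 1) % stride == 0:
            out[(step + 1) // stride, :] = y

    return STATUS_OK, n_steps, max_drift, max_err, sign_flips
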