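"""Compiled inner loops for dynamics and Monte Carlo sampling.

These reproduce the vectorized reference implementations in
:mod:`gbion.born` and :mod:`gbion.energy` with explicit pair loops so
numba can compile them; a unit test pins agreement between the two
paths. If numba is unavailable the plain-Python versions of the same
loops are used (slow but correct).
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap

R_MAX = 1000.0


@njit(cache=True)
def _descreen_scalar(d, rho_i, rho_j):
    """Pairwise descreening integral and d/dd; mirrors born._descreen_integral."""
    U = d + rho_j
    if U <= rho_i:
        return 0.0, 0.0
    if d >= rho_i + rho_j:
        L = d - rho_j
        Lp = 1.0
        engulf = False
    elif d + rho_i < rho_j:
        L = rho_j - d
        Lp = -1.0
        engulf = True
    else:
        L = rho_i
        Lp = 0.0
        engulf = False
    invL = 1.0 / L
    invU = 1.0 / U
    lnLU = math.log(L / U)
    term_lin = 0.25 * (d - rho_j * rho_j / d) * (invU * invU - invL * invL)
    I = 0.5 * (invL - invU + term_lin + lnLU / (2.0 * d))
    dterm = (0.25 * (1.0 + rho_j * rho_j / (d * d)) * (invU * invU - invL * invL)
             + 0.25 * (d - rho_j * rho_j / d)
             * (2.0 * Lp * invL ** 3 - 2.0 * invU ** 3))
    dI = 0.5 * (-Lp * invL * invL + invU * invU + dterm
                - lnLU / (2.0 * d * d)
                + (Lp * invL - invU) / (2.0 * d))
    if engulf:
        I += 1.0 / rho_i - invL
        dI += Lp * invL * invL
    return I, dI


@njit(cache=True)
def radii_kernel(pos, rho, solute, frozen_solute):
    """Effective radii, dI/dd pair table and live flags."""
    n = pos.shape[0]
    dI = np.zeros((n, n))
    radii = np.empty(n)
    live = np.ones(n, np.bool_)
    for i in range(n):
        if frozen_solute and solute[i]:
            live[i] = False
        S = 0.0
        for j in range(n):
            if j == i:
                continue
            if frozen_solute and solute[i] and not solute[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            I, dIij = _descreen_scalar(d, rho[i], rho[j])
            S += I
            if not (frozen_solute and solute[i]):
                dI[i, j] = dIij
        inv = 1.0 / rho[i] - S
        if inv < 1.0 / R_MAX:
            radii[i] = R_MAX
            live[i] = False
            for j in range(n):
                dI[i, j] = 0.0
        else:
            radii[i] = 1.0 / inv
    return radii, dI, live


@njit(cache=True)
def energy_forces_kernel(pos, q, rho, radii, dI, live, sigma, eps_lj, code,
                         gamma, eps_in, eps_out, ke, compute_forces):
    """Total pair-class GB + LJ energy and forces with the radii chain rule.

    Returns (coulomb, gb_cross, gb_self, lj, forces).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    A = np.zeros(n)               # dE/dR_i accumulators
    g_direct = np.zeros((n, n))   # dE/dd at fixed radii
    e_coul = 0.0
    e_cross = 0.0
    e_lj = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            ci = code[i]
            cj = code[j]
            G = gamma[ci, cj]
            EIN = eps_in[ci, cj]
            C = 1.0 / EIN - 1.0 / eps_out
            qq = q[i] * q[j]
            P = radii[i] * radii[j]
            if G > 0.0:
                x = d * d / (G * P)
                ex = math.exp(-x)
            else:
                x = 0.0
                ex = 0.0
            f = math.sqrt(d * d + P * ex)
            e_coul += ke * qq / (EIN * d)
            e_cross += -ke * C * qq / f
            sig = 0.5 * (sigma[i] + sigma[j])
            epsm = math.sqrt(eps_lj[i] * eps_lj[j])
            x6 = (sig / d) ** 6
            e_lj += 4.0 * epsm * (x6 * x6 - x6)
            if compute_forces:
                inv_f2 = 1.0 / (f * f)
                if G > 0.0:
                    df_dd = (d / f) * (1.0 - ex / G)
                    df_dP = ex * (1.0 + x) / (2.0 * f)
                else:
                    df_dd = d / f
                    df_dP = 0.0
                dE = ke * qq * (-1.0 / (EIN * d * d) + C * inv_f2 * df_dd)
                dE += 4.0 * epsm * (-12.0 * x6 * x6 + 6.0 * x6) / d
                g_direct[i, j] = dE
                g_direct[j, i] = dE
                dEdf = ke * C * qq * inv_f2
                A[i] += dEdf * df_dP * radii[j]
                A[j] += dEdf * df_dP * radii[i]
    e_self = 0.0
    for i in range(n):
        ein_d = eps_in[code[i], code[i]]
        cd = 1.0 / ein_d - 1.0 / eps_out
        e_self += -0.5 * ke * cd * q[i] * q[i] / radii[i]
        if compute_forces:
            A[i] += 0.5 * ke * cd * q[i] * q[i] / (radii[i] * radii[i])
    if compute_forces:
        for i in range(n):
            for j in range(i + 1, n):
                g = g_direct[i, j]
                if live[i]:
                    g += A[i] * radii[i] * radii[i] * dI[i, j]
                if live[j]:
                    g += A[j] * radii[j] * radii[j] * dI[j, i]
                if g != 0.0:
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    d = math.sqrt(dx * dx + dy * dy + dz * dz)
                    s = g / d
                    forces[i, 0] -= s * dx
                    forces[i, 1] -= s * dy
                    forces[i, 2] -= s * dz
                    forces[j, 0] += s * dx
                    forces[j, 1] += s * dy
                    forces[j, 2] += s * dz
    return e_coul, e_cross, e_self, e_lj, forces
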