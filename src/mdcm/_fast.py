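"""Numba-compiled batched Euler kernels for the two model families.

These are exact re-implementations of the numpy vector fields in
:mod:`mdcm.models`, specialised for fixed-step ensemble integration (the
hot loops behind trial generation and finite-difference sensitivities).
Equivalence with the numpy path is asserted in the test suite.  Rows that
blow up are zeroed and flagged instead of aborting the whole ensemble.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["decision_euler_batch", "rate_euler_batch"]


@njit(cache=True, fastmath=False)
def _sigm(z: float) -> float:
    if z > 60.0:
        z = 60.0
    elif z < -60.0:
        z = -60.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def decision_euler_batch(x0, u, wee, wei, He, Hi, Ke, Ki,
                         C1, C2, C3, C4, C5, C6, C7, r1, r2, tau_ampa,
                         shocks, amp, dt, stride, n_steps):
    """Batched forward-Euler / Euler-Maruyama of the decision model.

    ``x0 (B,32)``, ``u (n_steps+1, 2)`` stimulus currents, ``wee``/``wei``
    ``(B,2)`` extrinsic drive weights per target column, ``shocks``
    ``(B, n_steps, 4)`` standard-normal noise increments (empty array for
    the noise-free case), ``amp`` the Ito diffusion of the filtered noise
    channels.  Returns ``(traj (n_out,B,32), ok (B,))`` with the state
    recorded every ``stride`` steps; blown-up rows are zeroed and flagged.
    """
    B = x0.shape[0]
    n_out = n_steps // stride + 1
    traj = np.zeros((n_out, B, 32))
    ok = np.ones(B, dtype=np.bool_)
    x = x0.copy()
    for b in range(B):
        for j in range(32):
            traj[0, b, j] = x[b, j]
    base = 1.0 / (1.0 + np.exp(min(r1 * r2, 60.0)))
    HeKe = He * Ke
    HiKi = Hi * Ki
    Ke2 = Ke * Ke
    Ki2 = Ki * Ki
    sqdt = np.sqrt(dt)
    noisy = shocks.shape[1] > 0
    for k in range(n_steps):
        uk1 = u[k, 0]
        uk2 = u[k, 1]
        for b in range(B):
            if not ok[b]:
                continue
            # column order: [v(7), y(7)] x 2, then 4 noise states
            m1 = x[b, 1] - x[b, 2] + x[b, 6]
            m2 = x[b, 15] - x[b, 16] + x[b, 20]
            Sm1 = _sigm(r1 * (m1 - r2)) - base
            Sm2 = _sigm(r1 * (m2 - r2)) - base
            fine = True
            for col in range(2):
                o = 14 * col
                Sm = Sm1 if col == 0 else Sm2
                Smk = Sm2 if col == 0 else Sm1
                uk = uk1 if col == 0 else uk2
                drive_e1 = (C1 * Sm + wee[b, col] * Smk + uk
                            + x[b, 28 + 2 * col])
                drive_i = (C4 * Sm + wei[b, col] * Smk + uk
                           + x[b, 29 + 2 * col])
                S26 = _sigm(r1 * (x[b, o + 1] + x[b, o + 5] - r2)) - base
                Sff = _sigm(r1 * (x[b, o + 3] - x[b, o + 4] - r2)) - base
                S16 = _sigm(r1 * (x[b, o + 0] + x[b, o + 5] - r2)) - base
                v = x[b, o:o + 7]
                y = x[b, o + 7:o + 14]
                dy0 = HeKe * drive_e1 - 2 * Ke * y[0] - Ke2 * v[0]
                dy1 = HeKe * C2 * S26 - 2 * Ke * y[1] - Ke2 * v[1]
                dy2 = HiKi * C3 * Sff - 2 * Ki * y[2] - Ki2 * v[2]
                dy3 = HeKe * drive_i - 2 * Ke * y[3] - Ke2 * v[3]
                dy4 = HiKi * C5 * Sff - 2 * Ki * y[4] - Ki2 * v[4]
                dy5 = HeKe * C6 * S16 - 2 * Ke * y[5] - Ke2 * v[5]
                dy6 = HeKe * C7 * Sm - 2 * Ke * y[6] - Ke2 * v[6]
                for j in range(7):
                    x[b, o + j] = v[j] + dt * y[j]
                x[b, o + 7] = y[0] + dt * dy0
                x[b, o + 8] = y[1] + dt * dy1
                x[b, o + 9] = y[2] + dt * dy2
                x[b, o + 10] = y[3] + dt * dy3
                x[b, o + 11] = y[4] + dt * dy4
                x[b, o + 12] = y[5] + dt * dy5
                x[b, o + 13] = y[6] + dt * dy6
            for c in range(4):
                xn = x[b, 28 + c] - dt * x[b, 28 + c] / tau_ampa
                if noisy:
                    xn += sqdt * amp * shocks[b, k, c]
                x[b, 28 + c] = xn
            for j in range(32):
                if not np.isfinite(x[b, j]):
                    fine = False
                    break
            if not fine:
                ok[b] = False
                for j in range(32):
                    x[b, j] = 0.0
        if (k + 1) % stride == 0:
            ko = (k + 1) // stride
            for b in range(B):
                if ok[b]:
                    for j in range(32):
                        traj[ko, b, j] = x[b, j]
    return traj, ok


@njit(cache=True)
def rate_euler_batch(x0, I1, I2, wee, wei, tau_e, tau_i,
                     C1, C2, C3, C4, C5, C6, C7,
                     r1_max, r0, V_star, ge, gi, dt, stride, n_steps):
    """Batched forward-Euler of the 6-state rate model (constant drive)."""
    B = x0.shape[0]
    n_out = n_steps // stride + 1
    traj = np.zeros((n_out, B, 6))
    ok = np.ones(B, dtype=np.bool_)
    x = x0.copy()
    for b in range(B):
        for j in range(6):
            traj[0, b, j] = x[b, j]
    for k in range(n_steps):
        for b in range(B):
            if not ok[b]:
                continue
            Ve1_1, Ve2_1, Vi_1 = x[b, 0], x[b, 1], x[b, 2]
            Ve1_2, Ve2_2, Vi_2 = x[b, 3], x[b, 4], x[b, 5]
            re1_1 = r1_max * _sigm((Ve1_1 - V_star) / ge) + r0
            re2_1 = r1_max * _sigm((Ve2_1 - V_star) / ge) + r0
            ri_1 = r1_max * _sigm((Vi_1 - V_star) / gi) + r0
            re1_2 = r1_max * _sigm((Ve1_2 - V_star) / ge) + r0
            re2_2 = r1_max * _sigm((Ve2_2 - V_star) / ge) + r0
            ri_2 = r1_max * _sigm((Vi_2 - V_star) / gi) + r0
            d0 = -Ve1_1 / tau_e + C6 * re1_1 + C1 * re2_1 + I1
            d1 = (-Ve2_1 / tau_e + C7 * re2_1 + wee[b, 0] * re2_2
                  + C2 * re1_1 - C3 * ri_1)
            d2 = (-Vi_1 / tau_i + C4 * re2_1 + wei[b, 0] * re2_2
                  - C5 * ri_1 + I1)
            d3 = -Ve1_2 / tau_e + C6 * re1_2 + C1 * re2_2 + I2
            d4 = (-Ve2_2 / tau_e + C7 * re2_2 + wee[b, 1] * re2_1
                  + C2 * re1_2 - C3 * ri_2)
            d5 = (-Vi_2 / tau_i + C4 * re2_2 + wei[b, 1] * re2_1
                  - C5 * ri_2 + I2)
            x[b, 0] = Ve1_1 + dt * d0
            x[b, 1] = Ve2_1 + dt * d1
            x[b, 2] = Vi_1 + dt * d2
            x[b, 3] = Ve1_2 + dt * d3
            x[b, 4] = Ve2_2 + dt * d4
            x[b, 5] = Vi_2 + dt * d5
            fine = True
            for j in range(6):
                if not np.isfinite(x[b, j]):
                    fine = False
                    break
            if not fine:
                ok[b] = False
                for j in range(6):
                    x[b, j] = 0.0
        if (k + 1) % stride == 0:
            ko = (k + 1) // stride
            for b in range(B):
                if ok[b]:
                    for j in range(6):
                        traj[ko, b, j] = x[b, j]
    return traj, ok
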