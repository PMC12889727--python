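"""Compiled fixed-step RK4 kernels for ensembles of independent 3-D units.

Each reservoir unit is an autonomous 3-D flow; units never interact, so the
integration loop is a plain (sample, unit) nest that vectorizes well under
numba. ``fastmath`` is safe here because the kernels never branch on NaN;
non-finite blow-ups are detected by the callers on the returned arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

# State layout is unit-major: x[d, i, :] = (x_i, y_i, z_i) of unit i, sample d.


@njit(cache=True, fastmath=True, parallel=True)
def rk4_lorenz_final(x0, sigma, rho, beta, inv_tau, dt, n_steps):
    """Evolve (D, N, 3) initial states for n_steps and return the final states."""
    D, N, _ = x0.shape
    out = np.empty_like(x0)
    for d in prange(D):
        for i in range(N):
            x = x0[d, i, 0]
            y = x0[d, i, 1]
            z = x0[d, i, 2]
            s = sigma[i]
            r = rho[i]
            b = beta[i]
            it = inv_tau[i]
            h = dt
            for _ in range(n_steps):
                k1x = it * (s * (y - x))
                k1y = it * (x * (r - z) - y)
                k1z = it * (x * y - b * z)
                x2 = x + 0.5 * h * k1x
                y2 = y + 0.5 * h * k1y
                z2 = z + 0.5 * h * k1z
                k2x = it * (s * (y2 - x2))
                k2y = it * (x2 * (r - z2) - y2)
                k2z = it * (x2 * y2 - b * z2)
                x3 = x + 0.5 * h * k2x
                y3 = y + 0.5 * h * k2y
                z3 = z + 0.5 * h * k2z
                k3x = it * (s * (y3 - x3))
                k3y = it * (x3 * (r - z3) - y3)
                k3z = it * (x3 * y3 - b * z3)
                x4 = x + h * k3x
                y4 = y + h * k3y
                z4 = z + h * k3z
                k4x = it * (s * (y4 - x4))
                k4y = it * (x4 * (r - z4) - y4)
                k4z = it * (x4 * y4 - b * z4)
                x += h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
                y += h / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
                z += h / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
            out[d, i, 0] = x
            out[d, i, 1] = y
            out[d, i, 2] = z
    return out


@njit(cache=True, fastmath=True, parallel=True)
def rk4_lorenz_traj(x0, sigma, rho, beta, inv_tau, dt, n_steps, save_every):
    """As ``rk4_lorenz_final`` but also save every ``save_every``-th state.

    Returns (D, n_save, N, 3) with the initial state at index 0 and the final
    state at index -1 (n_steps must be a multiple of save_every).
    """
    D, N, _ = x0.shape
    n_save = n_steps // save_every + 1
    out = np.empty((D, n_save, N, 3))
    for d in prange(D):
        for i in range(N):
            x = x0[d, i, 0]
            y = x0[d, i, 1]
            z = x0[d, i, 2]
            s = sigma[i]
            r = rho[i]
            b = beta[i]
            it = inv_tau[i]
            h = dt
            out[d, 0, i, 0] = x
            out[d, 0, i, 1] = y
            out[d, 0, i, 2] = z
            for k in range(1, n_steps + 1):
                k1x = it * (s * (y - x))
                k1y = it * (x * (r - z) - y)
                k1z = it * (x * y - b * z)
                x2 = x + 0.5 * h * k1x
                y2 = y + 0.5 * h * k1y
                z2 = z + 0.5 * h * k1z
                k2x = it * (s * (y2 - x2))
                k2y = it * (x2 * (r - z2) - y2)
                k2z = it * (x2 * y2 - b * z2)
                x3 = x + 0.5 * h * k2x
                y3 = y + 0.5 * h * k2y
                z3 = z + 0.5 * h * k2z
                k3x = it * (s * (y3 - x3))
                k3y = it * (x3 * (r - z3) - y3)
                k3z = it * (x3 * y3 - b * z3)
                x4 = x + h * k3x
                y4 = y + h * k3y
                z4 = z + h * k3z
                k4x = it * (s * (y4 - x4))
                k4y = it * (x4 * (r - z4) - y4)
                k4z = it * (x4 * y4 - b * z4)
                x += h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
                y += h / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
                z += h / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
                if k % save_every == 0:
                    j = k // save_every
                    out[d, j, i, 0] = x
                    out[d, j, i, 1] = y
                    out[d, j, i, 2] = z
    return out


@njit(cache=True, fastmath=True, parallel=True)
def rk4_rossler_final(x0, a, b, c, inv_tau, dt, n_steps):
    """Fixed-step RK4 for an ensemble of independent Rössler units."""
    D, N, _ = x0.shape
    out = np.empty_like(x0)
    for d in prange(D):
        for i in range(N):
            x = x0[d, i, 0]
            y = x0[d, i, 1]
            z = x0[d, i, 2]
            ai = a[i]
            bi = b[i]
            ci = c[i]
            it = inv_tau[i]
            h = dt
            for _ in range(n_steps):
                k1x = it * (-y - z)
                k1y = it * (x + ai * y)
                k1z = it * (bi + z * (x - ci))
                x2 = x + 0.5 * h * k1x
                y2 = y + 0.5 * h * k1y
                z2 = z + 0.5 * h * k1z
                k2x = it * (-y2 - z2)
                k2y = it * (x2 + ai * y2)
                k2z = it * (bi + z2 * (x2 - ci))
                x3 = x + 0.5 * h * k2x
                y3 = y + 0.5 * h * k2y
                z3 = z + 0.5 * h * k2z
                k3x = it * (-y3 - z3)
                k3y = it * (x3 + ai * y3)
                k3z = it * (bi + z3 * (x3 - ci))
                x4 = x + h * k3x
                y4 = y + h * k3y
                z4 = z + h * k3z
                k4x = it * (-y4 - z4)
                k4y = it * (x4 + ai * y4)
                k4z = it * (bi + z4 * (x4 - ci))
                x += h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
                y += h / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
                z += h / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
            out[d, i, 0] = x
            out[d, i, 1] = y
            out[d, i, 2] = z
    return out
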