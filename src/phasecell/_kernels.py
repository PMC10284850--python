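"""Fused inner-loop kernels for the time stepper.

The semi-implicit step spends most of its time in pointwise algebra over
the (N, n, n) field stack; these kernels fuse that algebra into single
passes.  They are JIT-compiled with numba when available and fall back to
equivalent vectorised numpy otherwise.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in CI
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

from .energy import PRESENCE_HI, PRESENCE_LO, clamped_interaction_terms


@njit(cache=True, fastmath=True)
def _explicit_rhs_numba(phi, a, bulk_inv, in_inv, sigma, lo, hi, dx,
                        ex, ey, shear, active, w_static, B_static):
    N, n, _ = phi.shape
    M = n * n
    flat = phi.reshape(N, M)
    B = np.empty((N, M))
    w = np.empty((N, M))
    wp = np.empty((N, M))
    Wsum = w_static.copy()
    Bsum = B_static.copy()
    inv_span = 1.0 / (hi - lo)
    for i in range(N):
        for m in range(M):
            ph = flat[i, m]
            pcl = ph
            if pcl > 1.0:
                pcl = 1.0
            elif pcl < -1.0:
                pcl = -1.0
            Bi = 0.5 * (pcl + 1.0)
            u = 0.5 * (pcl - 1.0)
            u2 = u * u
            wraw = 1.0 - (a + 1.0) * u2 + a * u2 * u2
            t = (pcl - lo) * inv_span
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            s = t * t * (3.0 - 2.0 * t)
            wi = s * wraw
            if -1.0 <= ph <= 1.0:
                wpr = -(a + 1.0) * u + 2.0 * a * u2 * u
                wpi = 6.0 * t * (1.0 - t) * inv_span * wraw + s * wpr
            else:
                wpi = 0.0
            B[i, m] = Bi
            w[i, m] = wi
            wp[i, m] = wpi
            Wsum[m] += wi
            Bsum[m] += Bi
    mu = np.empty((N, M))
    for i in range(N):
        for m in range(M):
            ph = flat[i, m]
            Bp = 0.5 if (-1.0 <= ph <= 1.0) else 0.0
            mu[i, m] = ((ph * ph * ph - ph) * bulk_inv
                        + (Bp * (Wsum[m] - w[i, m])
                           + wp[i, m] * (Bsum[m] - B[i, m])) * in_inv
                        - sigma * ph)
    mu3 = mu.reshape(N, n, n)
    E = np.empty((N, n, n))
    inv_dx2 = 1.0 / (dx * dx)
    inv_2dx = 1.0 / (2.0 * dx)
    for i in range(N):
        for x in range(n):
            xp = x + 1 if x + 1 < n else 0
            xm = x - 1 if x >= 1 else n - 1
            for y in range(n):
                yp = y + 1 if y + 1 < n else 0
                ym = y - 1 if y >= 1 else n - 1
                lap = (mu3[i, xp, y] + mu3[i, xm, y] + mu3[i, x, yp]
                       + mu3[i, x, ym] - 4.0 * mu3[i, x, y]) * inv_dx2
                if active:
                    gxp = phi[i, xp, y] + 1.0
                    gxm = phi[i, xm, y] + 1.0
                    gyp = phi[i, x, yp] + 1.0
                    gym = phi[i, x, ym] + 1.0
                    adv = (ex[i] * (gxp * gxp - gxm * gxm)
                           + ey[i] * (gyp * gyp - gym * gym)) \
                        * 0.25 * inv_2dx
                else:
                    adv = shear[x] * (phi[i, x, yp]
                                      - phi[i, x, ym]) * inv_2dx
                E[i, x, y] = lap - adv
    return E


def _explicit_rhs_numpy(phi, a, bulk_inv, in_inv, sigma, lo, hi, dx,
                        ex, ey, shear, active, w_static, B_static):
    n = phi.shape[-1]
    B, w, wp, Bp = clamped_interaction_terms(phi, a)
    Wsum = w.sum(axis=0) + w_static.reshape(n, n)
    Bsum = B.sum(axis=0) + B_static.reshape(n, n)
    mu = ((phi**3 - phi) * bulk_inv
          + (Bp * (Wsum - w) + wp * (Bsum - B)) * in_inv - sigma * phi)
    lap = (np.roll(mu, 1, -2) + np.roll(mu, -1, -2) + np.roll(mu, 1, -1)
           + np.roll(mu, -1, -1) - 4.0 * mu) / dx**2
    if active:
        G = 0.25 * (phi + 1.0) ** 2
        gx = (np.roll(G, -1, -2) - np.roll(G, 1, -2)) / (2 * dx)
        gy = (np.roll(G, -1, -1) - np.roll(G, 1, -1)) / (2 * dx)
        adv = ex[:, None, None] * gx + ey[:, None, None] * gy
    else:
        adv = shear[None, :, None] * (
            np.roll(phi, -1, -1) - np.roll(phi, 1, -1)) / (2 * dx)
    return lap - adv


def explicit_rhs(phi: np.ndarray, a: float, bulk_inv: float, in_inv: float,
                 sigma: float, dx: float, ex: np.ndarray, ey: np.ndarray,
                 shear: np.ndarray, active: bool,
                 w_static: np.ndarray, B_static: np.ndarray) -> np.ndarray:
    """Real-space explicit right-hand side of the semi-implicit step:
    Lap_fd(mu_explicit) - v . grad(phi) in conservative centred-difference
    form (both terms telescope over the periodic grid, so per-cell mass is
    conserved to round-off).  ``ex``/``ey`` carry v0 e_i for the active
    mode; ``shear`` is the x-dependent speed for passive shear."""
    if HAVE_NUMBA:
        return _explicit_rhs_numba(phi, a, bulk_inv, in_inv, sigma,
                                   PRESENCE_LO, PRESENCE_HI, dx, ex, ey,
                                   shear, active, w_static, B_static)
    return _explicit_rhs_numpy(phi, a, bulk_inv, in_inv, sigma,
                               PRESENCE_LO, PRESENCE_HI, dx, ex, ey,
                               shear, active, w_static, B_static)


@njit(cache=True, fastmath=True)
def _shape_fd_numba(phi, dx):
    N, n, _ = phi.shape
    S0 = np.zeros(N)
    S1 = np.zeros(N)
    inv2 = 1.0 / (2.0 * dx)
    for i in range(N):
        s0 = 0.0
        s1 = 0.0
        for x in range(n):
            xp = x + 1 if x + 1 < n else 0
            xm = x - 1 if x >= 1 else n - 1
            for y in range(n):
                yp = y + 1 if y + 1 < n else 0
                ym = y - 1 if y >= 1 else n - 1
                gx = (phi[i, xp, y] - phi[i, xm, y]) * inv2
                gy = (phi[i, x, yp] - phi[i, x, ym]) * inv2
                s0 += gy * gy - gx * gx
                s1 -= gx * gy
        S0[i] = s0 * dx * dx / 8.0
        S1[i] = s1 * dx * dx / 4.0
    return S0, S1


def shape_components_fd(phi: np.ndarray, dx: float):
    """Centred-difference shape-tensor components for a field stack."""
    if HAVE_NUMBA:
        return _shape_fd_numba(phi, dx)
    gx = (np.roll(phi, -1, axis=-2) - np.roll(phi, 1, axis=-2)) / (2 * dx)
    gy = (np.roll(phi, -1, axis=-1) - np.roll(phi, 1, axis=-1)) / (2 * dx)
    da = dx * dx
    S0 = (gy**2 - gx**2).sum(axis=(-2, -1)) * (da / 8.0)
    S1 = -(gx * gy).sum(axis=(-2, -1)) * (da / 4.0)
    return S0, S1
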