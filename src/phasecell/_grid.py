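"""Shared periodic-grid helpers: spectral wavenumbers, gradients, torus
geometry.  Field arrays are indexed ``[..., ix, iy]`` with axis -2 the x1
direction and axis -1 the x2 direction, both periodic with spacing dx."""

from __future__ import annotations

import numpy as np


def wavenumbers(n: int, L: float):
    """Angular wavenumbers (kx, ky) for an n x n periodic grid of side L,
    laid out for ``rfft2`` (full along axis -2, half along axis -1)."""
    dx = L / n
    kx = 2 * np.pi * np.fft.fftfreq(n, d=dx)[:, None]
    ky = 2 * np.pi * np.fft.rfftfreq(n, d=dx)[None, :]
    return kx, ky


def spectral_gradient(field: np.ndarray, L: float):
    """Periodic spectral gradient (d/dx1, d/dx2) of real field(s)."""
    n = field.shape[-1]
    kx, ky = wavenumbers(n, L)
    fh = np.fft.rfft2(field)
    gx = np.fft.irfft2(1j * kx * fh, s=field.shape[-2:])
    gy = np.fft.irfft2(1j * ky * fh, s=field.shape[-2:])
    return gx, gy


def fd_gradient(field: np.ndarray, dx: float):
    """Centred-difference periodic gradient (fallback for non-power-of-two
    grids and the cheap path inside the time stepper)."""
    gx = (np.roll(field, -1, axis=-2) - np.roll(field, 1, axis=-2)) / (2 * dx)
    gy = (np.roll(field, -1, axis=-1) - np.roll(field, 1, axis=-1)) / (2 * dx)
    return gx, gy


def spectral_laplacian(field: np.ndarray, L: float):
    n = field.shape[-1]
    kx, ky = wavenumbers(n, L)
    fh = np.fft.rfft2(field)
    return np.fft.irfft2(-(kx**2 + ky**2) * fh, s=field.shape[-2:])


def grid_coords(n: int, L: float):
    """Cell-centre-free coordinates x in [0, L): x[i] = i*dx."""
    x = np.arange(n) * (L / n)
    return x[:, None], x[None, :]


def torus_delta(p: np.ndarray, q: np.ndarray, L: float) -> np.ndarray:
    """Minimal-image displacement p - q on the torus, in (-L/2, L/2]."""
    d = np.asarray(p, float) - np.asarray(q, float)
    return d - L * np.round(d / L)


def torus_distance(p, q, L: float):
    d = torus_delta(p, q, L)
    return np.sqrt((d**2).sum(axis=-1))


def periodic_centroid(weight: np.ndarray, L: float) -> np.ndarray:
    """Centroid of a non-negative weight field on the torus via the
    circular mean of each coordinate (well defined for any blob that does
    not wrap all the way around)."""
    n = weight.shape[-1]
    total = weight.sum()
    if total <= 0:
        raise ValueError("centroid of a non-positive weight field")
    ang = 2 * np.pi * np.arange(n) / n
    out = []
    for axis, other in ((0, 1), (1, 0)):
        w = weight.sum(axis=other)
        c = (w * np.cos(ang)).sum()
        s = (w * np.sin(ang)).sum()
        theta = np.arctan2(s, c) % (2 * np.pi)
        out.append(theta / (2 * np.pi) * L)
    return np.array(out)


def wrap_point(p: np.ndarray, L: float) -> np.ndarray:
    return np.mod(p, L)


def wrap_angle(theta):
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(theta) + np.pi) % (2 * np.pi) - np.pi)
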