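"""Free-energy functionals of the multi-phase field model.

The total free energy is F = F_CH + F_INT.  The Cahn--Hilliard part

    F_CH = (1/Ca) sum_i  ∫ (eps/2)|∇phi_i|^2 + (1/(4 eps))(phi_i^2 - 1)^2 dx

penalises interface length and drives phase separation of each field into
bulk values ±1; the interaction part

    F_INT = (1/In) sum_i ∫ B(phi_i) sum_{j != i} w(phi_j) dx

couples each cell's interior-and-interface indicator B(phi) = (phi+1)/2 to
every other cell through the quartic potential w.  With a = 1 the potential
is purely repulsive; a > 1 adds a shallow adhesive well (min w = -1/24 at
a = 1.5).
"""

from __future__ import annotations

import numpy as np

from ._grid import fd_gradient, spectral_gradient, spectral_laplacian
from .params import SimulationParams


def indicator_B(phi):
    """Interior-plus-interface indicator B(phi) = (phi + 1)/2."""
    return 0.5 * (np.asarray(phi) + 1.0)


def interaction_w(phi, a: float):
    """Pairwise interaction potential
    w(phi) = 1 - (a+1)((phi-1)/2)^2 + a((phi-1)/2)^4."""
    u2 = (0.5 * (np.asarray(phi) - 1.0)) ** 2
    return 1.0 - (a + 1.0) * u2 + a * u2 * u2


def interaction_w_prime(phi, a: float):
    """dw/dphi = -(a+1)(phi-1)/2 + a(phi-1)^3/4 (chain rule through
    u = (phi-1)/2)."""
    u = 0.5 * (np.asarray(phi) - 1.0)
    return -(a + 1.0) * u + 2.0 * a * u**3


# --- numerical regularisation of the interaction -------------------------
#
# Two adjustments make the interaction well posed on a single global grid
# (reference implementations solve each field on its own subdomain around
# the cell, which provides the same localisation implicitly):
#
# 1. B and w are evaluated on fields clamped to the physical range
#    [-1, 1], with derivatives vanishing outside it: the polynomial
#    extensions beyond the range are anti-restoring and would amplify the
#    small interface overshoot.
# 2. w carries a smooth presence factor s(phi) rising from 0 at the
#    exterior bulk value phi = -1 to 1 at phi = -0.7, so a field
#    contributes no interaction where it is absent.  For a > 1 the raw
#    potential has w'(-1) = 1 - a != 0, and without this localisation the
#    N exterior tails couple into a collectively unstable mode that
#    homogenises the monolayer.  The switch is deliberately wide: its
#    curvature (about 40, since the smoothstep endpoints sit where w is
#    near zero) stays below the stabilised splitting's coverage, while a
#    narrow switch would itself create an undamped stiff band.  The
#    overlap repulsion (phi > -0.63) is untouched; the adhesive well near
#    phi = -0.83 keeps roughly half its depth.

PRESENCE_LO = -1.0
PRESENCE_HI = -0.70


def presence_factor(phi):
    """Smoothstep in phi: 0 where the field is absent, 1 where present."""
    t = np.clip((np.asarray(phi) - PRESENCE_LO)
                / (PRESENCE_HI - PRESENCE_LO), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _presence_factor_prime(phi):
    t = np.clip((np.asarray(phi) - PRESENCE_LO)
                / (PRESENCE_HI - PRESENCE_LO), 0.0, 1.0)
    return 6.0 * t * (1.0 - t) / (PRESENCE_HI - PRESENCE_LO)


def _clamped(phi):
    return np.clip(phi, -1.0, 1.0)


def clamped_interaction_terms(phi: np.ndarray, a: float):
    """(B, w_eff, w_eff', B') entering the interaction energy and force:
    clamped fields, presence-localised w, primes masked off-range."""
    pc = _clamped(phi)
    in_range = np.abs(phi) <= 1.0
    B = indicator_B(pc)
    s = presence_factor(pc)
    w_raw = interaction_w(pc, a)
    w = s * w_raw
    wp = np.where(
        in_range,
        _presence_factor_prime(pc) * w_raw + s * interaction_w_prime(pc, a),
        0.0,
    )
    Bp = np.where(in_range, 0.5, 0.0)
    return B, w, wp, Bp


def _gradients(phi, L, method):
    if method == "spectral":
        return spectral_gradient(phi, L)
    n = phi.shape[-1]
    return fd_gradient(phi, L / n)


def ch_energy(phi: np.ndarray, params: SimulationParams,
              method: str = "spectral"):
    """Cahn--Hilliard energy of the stacked fields ``phi`` with shape
    (N, n, n) or (n, n).

    Returns ``(F_CH, density)`` where the density (summed over cells) is on
    the simulation grid and integrates to the scalar.
    """
    if phi.ndim == 2:
        phi = phi[None]
    gx, gy = _gradients(phi, params.L, method)
    eps = params.epsilon
    dens = (eps / 2.0) * (gx**2 + gy**2) + (phi**2 - 1.0) ** 2 / (4.0 * eps)
    density = dens.sum(axis=0) / params.Ca
    scalar = float(density.sum()) * params.dx**2
    return scalar, density


def interaction_energy(phi: np.ndarray, params: SimulationParams):
    """Interaction energy of the stacked fields (N, n, n).

    Returns ``(F_INT, density)`` with the density attributed at the field
    point: (1/In) sum_i B(phi_i) (W - w(phi_i)) where W = sum_j w(phi_j).
    """
    if phi.ndim == 2:
        phi = phi[None]
    B, w, _, _ = clamped_interaction_terms(phi, params.a)
    W = w.sum(axis=0)
    density = (B * (W - w)).sum(axis=0) / params.In
    scalar = float(density.sum()) * params.dx**2
    return scalar, density


def total_energy_density(phi: np.ndarray, params: SimulationParams,
                         include_interaction: bool = True,
                         method: str = "spectral") -> np.ndarray:
    """Pointwise free energy density f_total = f_ch (+ f_int)."""
    _, f_ch = ch_energy(phi, params, method=method)
    if not include_interaction:
        return f_ch
    _, f_int = interaction_energy(phi, params)
    return f_ch + f_int


def free_energy(phi: np.ndarray, params: SimulationParams,
                method: str = "spectral") -> float:
    """Scalar total free energy F = F_CH + F_INT."""
    f1, _ = ch_energy(phi, params, method=method)
    f2, _ = interaction_energy(phi, params)
    return f1 + f2


def chemical_potential(phi: np.ndarray, params: SimulationParams, i: int,
                       method: str = "spectral") -> np.ndarray:
    """Variational derivative dF/dphi_i on the grid.

    dF/dphi_i = (1/Ca)(-eps Lap phi_i + (phi_i^3 - phi_i)/eps)
              + (1/In)( B'(phi_i) sum_{j!=i} w(phi_j)
                        + w'(phi_i) sum_{j!=i} B(phi_j) ),

    with the interaction factors taken in their clamped, presence-
    localised form (see module comments) so the result is the exact
    Gateaux derivative of the energy this module reports.
    """
    if phi.ndim == 2:
        raise ValueError("chemical_potential needs the full field stack")
    p_i = phi[i]
    if method == "spectral":
        lap = spectral_laplacian(p_i, params.L)
    else:
        dx = params.dx
        lap = (
            np.roll(p_i, 1, 0) + np.roll(p_i, -1, 0)
            + np.roll(p_i, 1, 1) + np.roll(p_i, -1, 1) - 4 * p_i
        ) / dx**2
    mu = (-params.epsilon * lap + (p_i**3 - p_i) / params.epsilon) / params.Ca

    B, w, wp, Bp = clamped_interaction_terms(phi, params.a)
    w_others = w.sum(axis=0) - w[i]
    B_others = B.sum(axis=0) - B[i]
    mu += (Bp[i] * w_others + wp[i] * B_others) / params.In
    return mu
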