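"""Initial conditions and deterministic fixtures.

Confluent monolayers are seeded from a Lloyd-relaxed periodic Voronoi
tessellation: each cell takes the tanh profile of the signed distance to
its (inward-offset) Voronoi boundary, tanh(d / (sqrt(2) eps)), which is the
1D minimiser of the Cahn--Hilliard well and therefore starts the dynamics
near its slow manifold.  The inward offset (margin) controls the initial
extracellular space; it can be set either through a coverage factor c
(target cell area c L^2 / N) or calibrated directly to a measured gap
fraction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._grid import grid_coords, torus_delta
from .energy import indicator_B
from .params import SimulationParams
from .state import MonolayerState

__all__ = [
    "init_voronoi_monolayer", "init_t1_fixture", "fixture_confinement",
    "scripted_contact_sequence", "polygon_phase_field", "disk_phase_field",
]

#: Measured gap fractions of the two reference initialisations
#: (threshold 0.2 on sum_i B): nearly confluent "low gap" and the default
#: "high gap" condition used for the main analyses.
LOW_GAP_FRACTION = 0.00048
HIGH_GAP_FRACTION = 0.00212


def _hex_seeds(N: int, L: float, rng, jitter: float = 0.08) -> np.ndarray:
    """Perturbed hexagonal-ish lattice when N is a perfect square (with
    alternate-row offset), otherwise uniform random points."""
    m = int(round(np.sqrt(N)))
    if m * m == N and m % 2 == 0:
        s = L / m
        pts = []
        for r in range(m):
            off = 0.25 * s if r % 2 else -0.25 * s
            for c in range(m):
                pts.append(((c + 0.5) * s + off, (r + 0.5) * s))
        seeds = np.mod(np.array(pts), L)
    else:
        seeds = rng.uniform(0, L, size=(N, 2))
        return seeds
    seeds += rng.normal(0.0, jitter * s, size=seeds.shape)
    return np.mod(seeds, L)


def _ownership(seeds: np.ndarray, n: int, L: float) -> np.ndarray:
    """Nearest-seed label for every grid point under the torus metric."""
    x1, x2 = grid_coords(n, L)
    d2 = np.empty((len(seeds), n, n))
    for i, (sx, sy) in enumerate(seeds):
        ddx = torus_delta(x1, sx, L)
        ddy = torus_delta(x2, sy, L)
        d2[i] = ddx**2 + ddy**2
    return np.argmin(d2, axis=0)


def _lloyd(seeds: np.ndarray, n: int, L: float, iters: int) -> np.ndarray:
    """Lloyd relaxation of the periodic Voronoi seeds (centroids via
    minimal-image mean around the current seed)."""
    x1, x2 = grid_coords(n, L)
    for _ in range(iters):
        owner = _ownership(seeds, n, L)
        new = np.empty_like(seeds)
        for i, (sx, sy) in enumerate(seeds):
            mask = owner == i
            ddx = torus_delta(x1, sx, L)
            ddy = torus_delta(x2, sy, L)
            cnt = mask.sum()
            if cnt == 0:
                new[i] = seeds[i]
                continue
            mx = (np.broadcast_to(ddx, mask.shape)[mask]).mean()
            my = (np.broadcast_to(ddy, mask.shape)[mask]).mean()
            new[i] = np.mod([sx + mx, sy + my], L)
        seeds = new
    return seeds


def _signed_distances(owner: np.ndarray, seeds: np.ndarray,
                      L: float) -> np.ndarray:
    """Per-cell signed distance to the Voronoi boundary (positive inside),
    in physical units, periodic via recentring each cell."""
    n = owner.shape[0]
    dx = L / n
    d = np.empty((len(seeds), n, n))
    for i, (sx, sy) in enumerate(seeds):
        shift = (n // 2 - int(round(sx / dx)), n // 2 - int(round(sy / dx)))
        rolled = np.roll(owner == i, shift, axis=(0, 1))
        inside = ndimage.distance_transform_edt(rolled)
        outside = ndimage.distance_transform_edt(~rolled)
        # EDT measures pixel-centre to pixel-centre: shift both sides by
        # half a pixel so the signed field is continuous at the boundary
        signed = np.where(rolled, inside - 0.5, -(outside - 0.5)) * dx
        d[i] = np.roll(signed, (-shift[0], -shift[1]), axis=(0, 1))
    return d


def init_voronoi_monolayer(params: SimulationParams, rng,
                           coverage: float | None = None,
                           target_gap_fraction: float | None = None,
                           lloyd_iters: int = 5,
                           seeds: np.ndarray | None = None,
                           ) -> MonolayerState:
    """Build a confluent initial monolayer of N equal-area cells.

    Exactly one of ``coverage`` (c <= 1: per-cell target area c L^2/N) or
    ``target_gap_fraction`` (inward margin bisected until the measured gap
    fraction — the area fraction with sum_i B(phi_i) below
    ``params.gap_threshold`` — matches) controls the initial extracellular
    space.  Default: ``coverage = 0.97``, a nearly confluent packing whose
    slight slack leaves room for rearrangements.  Gap-fraction targets are
    meaningful at small interface widths relative to the cell radius;
    at desk-scale cell sizes they imply strongly over-shrunk cells, so the
    coverage route is the default.
    """
    if coverage is not None and target_gap_fraction is not None:
        raise ValueError("give either coverage or target_gap_fraction")
    if coverage is None and target_gap_fraction is None:
        coverage = 0.97
    n, L, N = params.grid_n, params.L, params.N
    dx = params.dx
    diam_pts = 2.0 * np.sqrt(params.cell_area / np.pi) / dx
    if diam_pts < 8:
        raise ValueError(
            f"N={N} too large for grid: cell diameter {diam_pts:.1f} grid "
            "points (< 8)"
        )
    if seeds is None:
        seeds = _lloyd(_hex_seeds(N, L, rng), n, L, lloyd_iters)
    else:
        seeds = np.mod(np.asarray(seeds, float), L)
        if seeds.shape != (N, 2):
            raise ValueError("seeds must have shape (N, 2)")
    owner = _ownership(seeds, n, L)
    d = _signed_distances(owner, seeds, L)
    width = np.sqrt(2.0) * params.epsilon

    if coverage is not None:
        if not 0 < coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        target = coverage * L**2 / N / dx**2  # target mass in grid cells
        phi = np.empty_like(d)
        for i in range(N):
            # bisect the inward margin so that the cell mass int B dx
            # hits the target exactly (monotone in the margin)
            lo, hi = float(d[i].min()), float(d[i].max())
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                mass = 0.5 * (np.tanh((d[i] - mid) / width) + 1.0).sum()
                if mass > target:
                    lo = mid
                else:
                    hi = mid
            phi[i] = np.tanh((d[i] - 0.5 * (lo + hi)) / width)
    else:
        def build(delta):
            return np.tanh((d - delta) / width)

        def gap_frac(delta):
            Bsum = indicator_B(build(delta)).sum(axis=0)
            return (Bsum < params.gap_threshold).mean()

        lo, hi = 0.0, 3.0 * params.epsilon
        while gap_frac(hi) < target_gap_fraction:
            hi *= 1.5
            if hi > L / 4:
                raise RuntimeError("cannot reach requested gap fraction")
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if gap_frac(mid) < target_gap_fraction:
                lo = mid
            else:
                hi = mid
        phi = build(0.5 * (lo + hi))

    theta = rng.uniform(0.0, 2.0 * np.pi, size=N)
    return MonolayerState(phi, _wrap_theta(theta), t=0.0)


def _wrap_theta(theta):
    return -((-np.asarray(theta) + np.pi) % (2 * np.pi) - np.pi)


def disk_phase_field(center, radius, params: SimulationParams) -> np.ndarray:
    """Single tanh disk profile on the periodic grid."""
    x1, x2 = grid_coords(params.grid_n, params.L)
    r = np.hypot(torus_delta(x1, center[0], params.L),
                 torus_delta(x2, center[1], params.L))
    return np.tanh((radius - r) / (np.sqrt(2.0) * params.epsilon))


def init_t1_fixture(params: SimulationParams,
                    relax_time: float = 0.5) -> MonolayerState:
    """Deterministic four-cell diamond primed for a single T1 exchange.

    Cells (A, B, C, D) = indices (0, 1, 2, 3).  B and D start in light
    contact along the +45 degree diagonal and A and C sit separated along
    the -45 degree diagonal, so the initial contact graph has the five
    relations {(A,B),(B,C),(C,D),(D,A),(B,D)}.  The propulsion angles are
    set so that B and D move apart while A and C move towards each other:
    run forward in active mode (with D_r = alpha = 0 for a fully
    deterministic trajectory) the island performs exactly one neighbour
    exchange, losing (B, D) first and gaining (A, C) a bounded time
    later.
    """
    if params.N != 4:
        raise ValueError("the T1 fixture uses exactly N=4 cells")
    L, eps = params.L, params.epsilon
    rho = L / 7.0
    # diffuse interfaces touch (contact threshold 0.15) out to separations
    # of about 2 rho + 2.45 eps; start the lost pair just inside and the
    # gained pair well outside that range
    s_bd = 1.8 * rho
    s_ac = 2.0 * rho + 3.5 * eps
    center = np.array([0.75 * L, 0.5 * L])
    u = np.array([1.0, 1.0]) / np.sqrt(2.0)   # B-D separation axis
    v = np.array([1.0, -1.0]) / np.sqrt(2.0)  # A-C approach axis
    centers = {
        0: center + 0.5 * s_ac * v,  # A
        1: center + 0.5 * s_bd * u,  # B
        2: center - 0.5 * s_ac * v,  # C
        3: center - 0.5 * s_bd * u,  # D
    }
    phi = np.stack([disk_phase_field(centers[i], rho, params)
                    for i in range(4)])
    theta = np.array([
        np.arctan2(-v[1], -v[0]),  # A heads towards C
        np.arctan2(u[1], u[0]),    # B heads outwards
        np.arctan2(v[1], v[0]),    # C heads towards A
        np.arctan2(-u[1], -u[0]),  # D heads outwards
    ])
    state = MonolayerState(phi, theta, t=0.0)
    if relax_time > 0:
        # settle the freshly assembled overlaps passively (no noise, no
        # propulsion) inside the confinement ring, so the active exchange
        # starts from a snug mechanical equilibrium
        from .dynamics import Simulation

        p_relax = params.replace(v0=0.0, D_r=0.0, alpha=0.0,
                                 mode="active", T=params.T)
        sim = Simulation(p_relax, state, seed=0,
                         static_phi=fixture_confinement(params))
        for _ in range(int(round(relax_time / params.tau))):
            sim.step()
        state = sim.state
        state.t = 0.0
    return state


def fixture_confinement(params: SimulationParams) -> np.ndarray:
    """Frozen ring of 'tissue' enclosing the four-cell fixture island.

    A static phase field that is +1 outside a circle around the cluster
    and -1 inside; passed to the integrator as a non-evolving interaction
    partner it plays the role of the surrounding monolayer, keeping the
    quadruple snug so the exchanging pair stays in contact until the
    exchange happens.
    """
    L, eps = params.L, params.epsilon
    rho = L / 7.0
    s_ac = 2.0 * rho + 3.5 * eps
    r_conf = 0.5 * s_ac + rho - 2.0 * eps
    x1, x2 = grid_coords(params.grid_n, L)
    center = np.array([0.75 * L, 0.5 * L])
    r = np.hypot(torus_delta(x1, center[0], L),
                 torus_delta(x2, center[1], L))
    return np.tanh((r - r_conf) / (np.sqrt(2.0) * eps))


def scripted_contact_sequence(relation_sets, times=None):
    """Build a contact-graph sequence verbatim from scripted relation sets
    (unit-test input for the T1 detector).

    ``relation_sets`` is a list of iterables of unordered cell-index
    pairs; ``times`` defaults to 0, 1, 2, ...
    """
    from .topology import ContactGraph

    if times is None:
        times = list(range(len(relation_sets)))
    if len(times) != len(relation_sets):
        raise ValueError("times and relation_sets differ in length")
    out = []
    for t, rels in zip(times, relation_sets):
        clean = set()
        for pair in rels:
            i, j = pair
            if i == j:
                raise ValueError(f"self-relation ({i}, {j}) is not allowed")
            clean.add((min(i, j), max(i, j)))
        out.append(ContactGraph(t=float(t), relations=frozenset(clean)))
    return out


def polygon_phase_field(vertices, params: SimulationParams,
                        center=None) -> np.ndarray:
    """tanh profile of the exact signed distance to a polygon, used as a
    sub-pixel-accurate rasterisation for shape measurements.

    ``vertices`` are polygon corners in physical units relative to
    ``center`` (default: domain centre); the polygon must fit well inside
    the domain (no periodic wrapping of the shape itself).
    """
    verts = np.asarray(vertices, float)
    if center is None:
        center = (params.L / 2, params.L / 2)
    verts = verts + np.asarray(center)
    x1, x2 = grid_coords(params.grid_n, params.L)
    px = np.broadcast_to(x1, (params.grid_n, params.grid_n)).ravel()
    py = np.broadcast_to(x2, (params.grid_n, params.grid_n)).ravel()
    pts = np.stack([px, py], axis=1)

    vmin = np.full(len(pts), np.inf)
    crossings = np.zeros(len(pts), dtype=int)
    for k in range(len(verts)):
        a = verts[k]
        b = verts[(k + 1) % len(verts)]
        ab = b - a
        ap = pts - a
        tpar = np.clip((ap @ ab) / (ab @ ab), 0.0, 1.0)
        proj = a + tpar[:, None] * ab
        vmin = np.minimum(vmin, np.linalg.norm(pts - proj, axis=1))
        # even-odd rule on a horizontal ray in +x2
        cond = (a[1] > pts[:, 1]) != (b[1] > pts[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = a[0] + (pts[:, 1] - a[1]) / ab[1] * ab[0]
        crossings += (cond & (pts[:, 0] < x_int)).astype(int)
    inside = crossings % 2 == 1
    sdf = np.where(inside, vmin, -vmin).reshape(params.grid_n, params.grid_n)
    return np.tanh(sdf / (np.sqrt(2.0) * params.epsilon))
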