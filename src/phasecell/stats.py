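"""Event-aligned statistics of T1 transitions.

The central diagnostic is the coarse-grained free energy density
f_{r_avg}: the disk average (radius r_avg = 0.02 L by default) of the
pointwise energy density.  Sampling f_{r_avg} at an event's epicenter over
time and averaging over events, aligned so that negative times precede the
event start and positive times follow the event end, yields the
characteristic asymmetric T1 energy profile: a fast rise to a peak at the
transition, a sudden drop, then a slow relaxation back toward the domain
mean.  The same alignment machinery is applied to the shape index and the
centre-of-mass speed of the four participating cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import griddata
from skimage import measure

from ._grid import grid_coords, periodic_centroid, torus_delta, wrap_point
from .dynamics import _shape_components
from .energy import indicator_B, total_energy_density
from .params import SimulationParams
from .state import MonolayerState
from .topology import T1Event, cell_centers, geometric_median

__all__ = [
    "coarse_grain", "coarse_energy_series", "sample_field",
    "annotate_events", "EventProfile", "event_energy_profile",
    "event_shape_velocity_profiles", "profile_crossings",
    "profile_asymmetry", "GammaFit", "DurationStats", "duration_stats",
    "duration_vs_max_energy", "shape_index", "diffuse_perimeter",
    "compute_observables", "gap_fraction", "tissue_flow_field",
    "group_com_trajectory", "chain_candidates",
]


# ---------------------------------------------------------------------------
# coarse-grained energy
# ---------------------------------------------------------------------------

def _disk_kernel_hat(n: int, L: float, r_avg: float):
    x1, x2 = grid_coords(n, L)
    dmin = torus_delta(x1, 0.0, L)
    dmin2 = torus_delta(x2, 0.0, L)
    disk = (dmin**2 + dmin2**2) < r_avg**2
    kernel = disk / disk.sum()  # centred at index (0, 0) via minimal image
    return np.fft.rfft2(kernel)


def coarse_grain(f: np.ndarray, params: SimulationParams,
                 r_avg: float | None = None) -> np.ndarray:
    """Periodic disk average of a scalar field.

    Convolution with the normalised disk indicator of radius ``r_avg``
    (default ``params.r_avg``); exactly preserves the spatial mean.
    """
    if r_avg is None:
        r_avg = params.r_avg
    if r_avg < params.dx:
        raise ValueError(
            f"r_avg={r_avg:.4g} is below the grid spacing {params.dx:.4g}"
        )
    khat = _disk_kernel_hat(f.shape[-1], params.L, r_avg)
    return np.fft.irfft2(np.fft.rfft2(f) * khat, s=f.shape[-2:])


def coarse_energy_series(snapshots, params: SimulationParams,
                         r_avg: float | None = None,
                         include_interaction: bool = True):
    """Coarse-grained total energy field for every snapshot.

    Returns an array of shape (n_saves, n, n).
    """
    out = np.empty((len(snapshots), params.grid_n, params.grid_n))
    for k, snap in enumerate(snapshots):
        f = total_energy_density(snap.phi, params,
                                 include_interaction=include_interaction)
        out[k] = coarse_grain(f, params, r_avg=r_avg)
    return out


def sample_field(field: np.ndarray, point, L: float) -> float:
    """Periodic bilinear interpolation of a grid field at a point."""
    n = field.shape[-1]
    g = np.asarray(point, float) / L * n
    i0 = np.floor(g).astype(int)
    frac = g - i0
    i0 = i0 % n
    i1 = (i0 + 1) % n
    f00 = field[i0[0], i0[1]]
    f10 = field[i1[0], i0[1]]
    f01 = field[i0[0], i1[1]]
    f11 = field[i1[0], i1[1]]
    return float(
        f00 * (1 - frac[0]) * (1 - frac[1]) + f10 * frac[0] * (1 - frac[1])
        + f01 * (1 - frac[0]) * frac[1] + f11 * frac[0] * frac[1]
    )


def annotate_events(events, result, coarse_fields=None,
                    params: SimulationParams | None = None):
    """Fill in each event's epicenter and peak coarse energy.

    ``result`` is a :class:`~phasecell.dynamics.SimulationResult`;
    ``coarse_fields`` may be precomputed with
    :func:`coarse_energy_series`.  max_energy is the peak of f_{r_avg}
    sampled at the (fixed) epicenter over the event's saved times.
    """
    if params is None:
        params = result.params
    times = np.asarray(result.times)
    if coarse_fields is None:
        coarse_fields = coarse_energy_series(result.snapshots, params)
    for ev in events:
        k_mid = int(np.argmin(np.abs(times - ev.t_mid)))
        centers = cell_centers(result.snapshots[k_mid], params)
        ev.epicenter = geometric_median(centers[list(ev.cells)], params.L)
        inside = np.where((times >= ev.t_start - 1e-9)
                          & (times <= ev.t_end + 1e-9))[0]
        ev.max_energy = max(
            sample_field(coarse_fields[k], ev.epicenter, params.L)
            for k in inside
        )
    return events


# ---------------------------------------------------------------------------
# event-aligned profiles
# ---------------------------------------------------------------------------

@dataclass
class EventProfile:
    """Event-aligned mean profile of a scalar observable.

    ``t_rel`` contains multiples of tau_save; negative entries are relative
    to event starts, positive entries relative to event ends, and the two
    zeros (start and end values) are reported separately so the in-event
    discontinuity is preserved.  ``during_frac``/``during_mean`` resample
    the in-event samples onto a normalised 0-100% duration grid.
    """

    t_rel: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_events: np.ndarray
    start_value: float
    end_value: float
    during_frac: np.ndarray
    during_mean: np.ndarray
    during_std: np.ndarray
    baseline: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_rel": self.t_rel, "mean": self.mean,
                             "std": self.std, "n": self.n_events})


def _aligned_profile(events, value_at, times, params, window, baseline,
                     n_during: int = 21) -> EventProfile:
    tau_save = params.tau_save
    times = np.asarray(times)
    t0, t_last = times[0], times[-1]
    n_bins = int(round(window / tau_save))

    pre = [[] for _ in range(n_bins + 1)]   # bin m: t_rel = -m*tau_save
    post = [[] for _ in range(n_bins + 1)]  # bin m: t_rel = +m*tau_save
    during = []
    for ev in events:
        for m in range(n_bins + 1):
            t = ev.t_start - m * tau_save
            if t >= t0 - 1e-9:
                v = value_at(ev, t)
                if v is not None and np.isfinite(v):
                    pre[m].append(v)
            t = ev.t_end + m * tau_save
            if t <= t_last + 1e-9:
                v = value_at(ev, t)
                if v is not None and np.isfinite(v):
                    post[m].append(v)
        dur_t = [t for t in times
                 if ev.t_start - 1e-9 <= t <= ev.t_end + 1e-9]
        vals = [value_at(ev, t) for t in dur_t]
        fracs = [(t - ev.t_start) / max(ev.duration, 1e-12) for t in dur_t]
        good = [(f, v) for f, v in zip(fracs, vals)
                if v is not None and np.isfinite(v)]
        if len(good) >= 2:
            f, v = map(np.asarray, zip(*good))
            grid = np.linspace(0.0, 1.0, n_during)
            during.append(np.interp(grid, f, v))

    def collapse(bins, sign):
        t_rel, mean, std, n = [], [], [], []
        for m, vals in enumerate(bins):
            if m == 0 or not vals:
                continue
            t_rel.append(sign * m * tau_save)
            mean.append(np.mean(vals))
            std.append(np.std(vals))
            n.append(len(vals))
        return t_rel, mean, std, n

    tp, mp, sp, np_pre = collapse(pre, -1)
    tq, mq, sq, nq = collapse(post, +1)
    t_rel = np.array(tp[::-1] + tq)
    mean = np.array(mp[::-1] + mq)
    std = np.array(sp[::-1] + sq)
    n_ev = np.array(np_pre[::-1] + nq)

    during_arr = np.array(during) if during else np.empty((0, n_during))
    return EventProfile(
        t_rel=t_rel, mean=mean, std=std, n_events=n_ev,
        start_value=float(np.mean(pre[0])) if pre[0] else np.nan,
        end_value=float(np.mean(post[0])) if post[0] else np.nan,
        during_frac=np.linspace(0.0, 100.0, n_during),
        during_mean=during_arr.mean(axis=0) if len(during_arr) else
        np.full(n_during, np.nan),
        during_std=during_arr.std(axis=0) if len(during_arr) else
        np.full(n_during, np.nan),
        baseline=baseline,
    )


def event_energy_profile(events, coarse_fields, times,
                         params: SimulationParams,
                         window: float = 20.0) -> EventProfile:
    """Mean f_{r_avg} at the epicenters, aligned to event start/end.

    In-event samples are excluded from the time-relative profile (they
    appear in the normalised during-event profile instead), producing the
    characteristic discontinuity at t_rel = 0.
    """
    times = np.asarray(times)
    idx = {round(t / params.tau_save): k for k, t in enumerate(times)}

    def value_at(ev, t):
        k = idx.get(round(t / params.tau_save))
        if k is None:
            return None
        return sample_field(coarse_fields[k], ev.epicenter, params.L)

    baseline = float(np.mean([f.mean() for f in coarse_fields]))
    return _aligned_profile(events, value_at, times, params, window,
                            baseline)


def event_shape_velocity_profiles(events, observables: pd.DataFrame,
                                  params: SimulationParams,
                                  window: float = 20.0):
    """Event-aligned profiles of the mean shape index and mean CoM speed
    of each event's four cells.  Returns ``(shape_profile,
    speed_profile)``."""
    times = np.sort(observables["t"].unique())
    piv_shape = observables.pivot_table(index="t", columns="cell",
                                        values="shape_index")
    piv_speed = observables.pivot_table(index="t", columns="cell",
                                        values="speed")

    def make(piv, baseline):
        def value_at(ev, t):
            k = round(t / params.tau_save) * params.tau_save
            try:
                row = piv.loc[k]
            except KeyError:
                return None
            return float(row[list(ev.cells)].mean())

        return _aligned_profile(events, value_at, times, params, window,
                                baseline)

    return (make(piv_shape, float(piv_shape.stack().mean())),
            make(piv_speed, float(piv_speed.stack().mean())))


def profile_crossings(profile: EventProfile, frac: float = 0.75):
    """Times where the mean profile crosses ``frac`` of its peak: the last
    pre-event crossing (rising) and the first post-event crossing
    (falling).  Returns ``(t_pre, t_post)`` (either may be None)."""
    peak = max(np.nanmax(profile.mean),
               profile.start_value, profile.end_value)
    level = frac * peak
    pre_mask = profile.t_rel < 0
    post_mask = profile.t_rel > 0
    t_pre = t_post = None
    tp = np.append(profile.t_rel[pre_mask], 0.0)
    vp = np.append(profile.mean[pre_mask], profile.start_value)
    below = np.where(vp < level)[0]
    if len(below) and below[-1] < len(vp) - 1:
        i = below[-1]
        t_pre = float(np.interp(level, [vp[i], vp[i + 1]],
                                [tp[i], tp[i + 1]]))
    tq = np.insert(profile.t_rel[post_mask], 0, 0.0)
    vq = np.insert(profile.mean[post_mask], 0, profile.end_value)
    below = np.where(vq < level)[0]
    if len(below):
        i = below[0]
        if i > 0:
            t_post = float(np.interp(-level, [-vq[i - 1], -vq[i]],
                                     [tq[i - 1], tq[i]]))
    return t_pre, t_post


def profile_asymmetry(profile: EventProfile, level_frac: float = 0.25):
    """Rise/decay times of the mean profile relative to the domain-mean
    baseline.

    The reference level is baseline + level_frac*(peak - baseline); the
    rise time is how long before the event the profile last sat at that
    level, the decay time how long after the event it first returns to it.
    A decay time exceeding the rise time quantifies the slow post-event
    relaxation.  Returns ``(rise_time, decay_time)`` (None if the profile
    never reaches the level inside the window).
    """
    peak = max(np.nanmax(profile.mean),
               profile.start_value, profile.end_value)
    level = profile.baseline + level_frac * (peak - profile.baseline)
    pre_mask = profile.t_rel < 0
    post_mask = profile.t_rel > 0
    rise = decay = None
    tp = profile.t_rel[pre_mask]
    vp = profile.mean[pre_mask]
    below = np.where(vp <= level)[0]
    if len(below):
        rise = float(-tp[below[-1]])
    tq = profile.t_rel[post_mask]
    vq = profile.mean[post_mask]
    below = np.where(vq <= level)[0]
    if len(below):
        decay = float(tq[below[0]])
    return rise, decay


# ---------------------------------------------------------------------------
# durations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood Gamma fit (location fixed at zero)."""

    shape: float
    scale: float
    loglik: float
    n: int

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma parameters must be positive")


@dataclass
class DurationStats:
    mean: float
    n: int
    fit: GammaFit | None
    degenerate: bool = False


def duration_stats(durations, min_fit: int = 5) -> DurationStats:
    """Summary and Gamma MLE of event durations.

    All-equal samples (or fewer than ``min_fit``) yield the summary with
    the fit flagged degenerate.
    """
    d = np.asarray([float(x) for x in durations])
    if d.size == 0:
        raise ValueError("no durations")
    mean = float(d.mean())
    if d.size < min_fit or np.ptp(d) == 0:
        return DurationStats(mean=mean, n=d.size, fit=None, degenerate=True)
    shape, _, scale = sps.gamma.fit(d, floc=0)
    loglik = float(sps.gamma.logpdf(d, shape, 0, scale).sum())
    return DurationStats(mean=mean, n=d.size,
                         fit=GammaFit(shape, scale, loglik, d.size))


def duration_vs_max_energy(events):
    """Per-event (max_energy, duration) table plus Spearman rank
    correlation (NaN when undefined)."""
    table = pd.DataFrame({
        "max_energy": [ev.max_energy for ev in events],
        "duration": [ev.duration for ev in events],
    })
    if len(table) < 3 or table["duration"].nunique() < 2 \
            or table["max_energy"].nunique() < 2:
        return table, float("nan")
    rho = sps.spearmanr(table["max_energy"], table["duration"]).statistic
    return table, float(rho)


# ---------------------------------------------------------------------------
# per-cell observables
# ---------------------------------------------------------------------------

def _main_contour(field: np.ndarray, level: float) -> np.ndarray:
    contours = measure.find_contours(field, level)
    closed = [c for c in contours
              if np.allclose(c[0], c[-1], atol=1e-8) and len(c) > 3]
    if not closed:
        raise ValueError("no closed level contour found")
    return max(closed, key=len)


def shape_index(field: np.ndarray, params: SimulationParams,
                level: float = 0.0, recenter: bool = True) -> float:
    """perimeter / sqrt(area) of the ``level`` contour of a field.

    The contour is extracted by marching squares after rolling the blob to
    the domain centre (periodic-aware); 2*sqrt(pi) = 3.5449 for a disk.
    """
    f = np.asarray(field, float)
    n = f.shape[0]
    if recenter:
        c = periodic_centroid(np.clip(f - level, 0, None) + 1e-30, params.L)
        shift = (n // 2 - int(round(c[0] / params.dx)),
                 n // 2 - int(round(c[1] / params.dx)))
        f = np.roll(f, shift, axis=(0, 1))
    contour = _main_contour(f, level)
    seg = np.diff(contour, axis=0)
    perimeter = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) * params.dx
    x, y = contour[:, 0], contour[:, 1]
    area = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])) * params.dx**2
    if area <= 0:
        raise ValueError("degenerate contour (zero area)")
    return perimeter / np.sqrt(area)


def diffuse_perimeter(phi_i: np.ndarray, params: SimulationParams) -> float:
    """Diffuse-interface perimeter estimate ∫|grad B| dx (cross-check for
    the contour measurement)."""
    from ._grid import spectral_gradient
    gx, gy = spectral_gradient(indicator_B(phi_i), params.L)
    return float(np.hypot(gx, gy).sum()) * params.dx**2


def compute_observables(snapshots, times, params: SimulationParams,
                        ) -> pd.DataFrame:
    """Per-cell per-save observables: periodic centroid, area, perimeter,
    shape index, shape-tensor components, propulsion angle and CoM
    velocity (backward difference of the unwrapped centroid)."""
    rows = []
    prev_centers = None
    for t, snap in zip(times, snapshots):
        B = indicator_B(snap.phi)
        S0, S1 = _shape_components(snap.phi, params, method="fd")
        centers = np.stack([periodic_centroid(B[i], params.L)
                            for i in range(snap.n_cells)])
        for i in range(snap.n_cells):
            area = float(B[i].sum()) * params.dx**2
            try:
                si = shape_index(snap.phi[i], params)
                per = si * np.sqrt(area)
            except ValueError:
                si, per = np.nan, np.nan
            if prev_centers is None:
                vx = vy = np.nan
            else:
                d = torus_delta(centers[i], prev_centers[i], params.L)
                vx, vy = d / params.tau_save
            rows.append(dict(
                t=t, cell=i, x=centers[i][0], y=centers[i][1], area=area,
                perimeter=per, shape_index=si, S0=float(S0[i]),
                S1=float(S1[i]), lam_plus=float(np.hypot(S0[i], S1[i])),
                theta=float(snap.theta[i]), vx=vx, vy=vy,
                speed=float(np.hypot(vx, vy)) if np.isfinite(vx) else np.nan,
            ))
        prev_centers = centers
    return pd.DataFrame(rows)


def gap_fraction(state: MonolayerState, params: SimulationParams) -> float:
    """Fraction of the domain where sum_i B(phi_i) falls below the gap
    threshold (extracellular space at tri-junctions and rosettes)."""
    Bsum = indicator_B(state.phi).sum(axis=0)
    return float((Bsum < params.gap_threshold).mean())


# ---------------------------------------------------------------------------
# tissue-scale flow
# ---------------------------------------------------------------------------

def tissue_flow_field(centers: np.ndarray, velocities: np.ndarray,
                      contacts, params: SimulationParams):
    """Continuous tissue velocity field from cell CoM velocities.

    Each cell's velocity is first averaged with its contact-graph
    neighbours (and itself), then interpolated to the grid by periodic
    linear interpolation (3x3 tiling of the sample points); degenerate
    geometries fall back to nearest-neighbour interpolation.  Returns
    ``(vx_grid, vy_grid, fallback_used)``.
    """
    centers = np.asarray(centers, float)
    velocities = np.asarray(velocities, float)
    if len(centers) < 3:
        raise ValueError("need at least three cells")
    from .topology import ContactGraph

    g = contacts.graph() if isinstance(contacts, ContactGraph) else contacts
    smoothed = np.empty_like(velocities)
    for i in range(len(centers)):
        nbrs = [i] + (list(g.neighbors(i)) if i in g else [])
        smoothed[i] = velocities[nbrs].mean(axis=0)

    L, n = params.L, params.grid_n
    offsets = np.array([(ax, ay) for ax in (-L, 0, L) for ay in (-L, 0, L)])
    tiled = (centers[None, :, :] + offsets[:, None, :]).reshape(-1, 2)
    vals = np.tile(smoothed, (9, 1))
    x1, x2 = grid_coords(n, L)
    xi = np.stack(np.broadcast_arrays(x1, x2), axis=-1).reshape(-1, 2)
    fallback = False
    try:
        out = griddata(tiled, vals, xi, method="linear")
        if np.isnan(out).any():
            raise ValueError("interpolation holes")
    except Exception:
        out = griddata(tiled, vals, xi, method="nearest")
        fallback = True
    out = out.reshape(n, n, 2)
    return out[..., 0], out[..., 1], fallback


def group_com_trajectory(observables: pd.DataFrame, cells,
                         params: SimulationParams) -> np.ndarray:
    """Unwrapped trajectory of the centre of mass of a named cell group,
    shape (n_saves, 2).  The first point is wrapped into [0, L)^2 and the
    rest accumulate minimal-image increments."""
    cells = list(cells)
    sub = observables[observables["cell"].isin(cells)]
    piv_x = sub.pivot_table(index="t", columns="cell", values="x")
    piv_y = sub.pivot_table(index="t", columns="cell", values="y")
    n_t = len(piv_x)
    traj = np.empty((n_t, 2))
    # unwrap each cell's path, then average
    ux = np.asarray(piv_x)
    uy = np.asarray(piv_y)
    for arr in (ux, uy):
        inc = np.diff(arr, axis=0)
        inc -= params.L * np.round(inc / params.L)
        arr[1:] = arr[0] + np.cumsum(inc, axis=0)
    traj[:, 0] = ux.mean(axis=1)
    traj[:, 1] = uy.mean(axis=1)
    return traj


def chain_candidates(events, r_chain: float, dt_chain: float,
                     params: SimulationParams):
    """Single-linkage chains of events: two events link when their
    epicenters lie within ``r_chain`` (torus metric) and their start times
    differ by 0 < dt < ``dt_chain``.  Returns a list of chains, each an
    event list ordered by start time."""
    events = sorted(events, key=lambda e: e.t_start)
    n = len(events)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            dt = events[j].t_start - events[i].t_start
            if not (0 < dt < dt_chain):
                continue
            d = np.linalg.norm(torus_delta(events[i].epicenter,
                                           events[j].epicenter, params.L))
            if d < r_chain:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(events[i])
    return sorted(groups.values(), key=lambda ch: ch[0].t_start)
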