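"""Contact graphs and T1 neighbour-exchange detection.

Two cells are in contact when their diffuse interfaces overlap materially:
max over the grid of min(B(phi_i), B(phi_j)) >= contact_threshold.  A T1
transition among four cells (A, B, C, D) is the signature

    {(A,B),(B,C),(C,D),(D,A),(B,D)}  ->  the four perimeter relations
                                     ->  {(A,B),(B,C),(C,D),(D,A),(A,C)}

i.e. the relation count among the quadruple drops from 5 to 4 and returns
to 5 with the other diagonal.  The event's duration is the time between
the last snapshot in which the lost diagonal was present and the first
snapshot in which the gained diagonal is present; its epicenter is the
geometric median of the four cell centres at the temporal midpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from ._grid import periodic_centroid, torus_delta, wrap_point
from .energy import indicator_B
from .params import SimulationParams
from .state import MonolayerState

__all__ = [
    "ContactGraph", "T1Event", "contact_graph", "detect_t1",
    "cell_centers", "epicenter", "geometric_median",
]


@dataclass(frozen=True)
class ContactGraph:
    """Time-stamped set of unordered neighbour relations."""

    t: float
    relations: frozenset

    def __post_init__(self):
        for i, j in self.relations:
            if i == j:
                raise ValueError(f"self-relation ({i}, {j})")
        norm = frozenset((min(i, j), max(i, j)) for i, j in self.relations)
        object.__setattr__(self, "relations", norm)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.relations)
        return g


@dataclass
class T1Event:
    """A detected neighbour exchange.

    ``cells`` lists the quadruple in cyclic (perimeter) order A, B, C, D;
    ``lost_pair`` (B, D) and ``gained_pair`` (A, C) are the two disjoint
    diagonals.  ``epicenter`` and ``max_energy`` are filled in by
    :func:`phasecell.stats.annotate_events`.
    """

    cells: tuple
    lost_pair: tuple
    gained_pair: tuple
    t_start: float
    t_end: float
    epicenter: np.ndarray | None = None
    max_energy: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def contact_graph(state: MonolayerState, params: SimulationParams,
                  ) -> ContactGraph:
    """Contact relations of all cell pairs in one snapshot."""
    B = indicator_B(state.phi)
    thr = params.contact_threshold
    # bounding prefilter: a pair can only touch where both B fields exceed
    # the threshold somewhere, so intersect their support masks.
    supports = B >= thr
    rels = set()
    for i, j in itertools.combinations(range(state.n_cells), 2):
        overlap = supports[i] & supports[j]
        if not overlap.any():
            continue
        if np.minimum(B[i][overlap], B[j][overlap]).max() >= thr:
            rels.add((i, j))
    return ContactGraph(t=state.t, relations=frozenset(rels))


class _Candidate:
    __slots__ = ("pair", "common", "perimeter_ok", "t_loss", "idx_loss")

    def __init__(self, pair, common, t_loss, idx_loss):
        self.pair = pair
        self.common = common
        self.t_loss = t_loss
        self.idx_loss = idx_loss


def detect_t1(graphs) -> list:
    """Detect T1 events in a uniformly sampled contact-graph sequence.

    Tracking is per lost pair: when a relation (B, D) disappears, the
    common neighbours of B and D at the last time the relation was present
    are candidate gain partners; the event closes at the first snapshot in
    which a previously unconnected pair (A, C) of those common neighbours
    bonds with the four perimeter relations intact at both endpoints.  If
    (B, D) reappears first, the candidate is a reversal and is discarded.
    Candidates unresolved at the end of the sequence are dropped.
    """
    graphs = list(graphs)
    events = []
    open_candidates: list[_Candidate] = []
    for k in range(1, len(graphs)):
        prev, cur = graphs[k - 1], graphs[k]

        still_open = []
        for cand in open_candidates:
            if cand.pair in cur.relations:
                continue  # reversal: discard
            ev = _try_close(cand, cur, graphs)
            if ev is not None:
                events.append(ev)
            else:
                still_open.append(cand)
        open_candidates = still_open

        g_prev = prev.graph()
        for pair in prev.relations - cur.relations:
            b, d = pair
            if b not in g_prev or d not in g_prev:
                continue
            common = sorted(set(g_prev.neighbors(b))
                            & set(g_prev.neighbors(d)))
            if len(common) < 2:
                continue
            cand = _Candidate(pair, common, prev.t, k - 1)
            ev = _try_close(cand, cur, graphs)
            if ev is not None:
                events.append(ev)
            else:
                open_candidates.append(cand)
    events.sort(key=lambda e: (e.t_start, e.t_end))
    return events


def _try_close(cand: _Candidate, cur: ContactGraph, graphs) -> T1Event | None:
    b, d = cand.pair
    loss_rels = graphs[cand.idx_loss].relations
    for a, c in itertools.combinations(cand.common, 2):
        gained = (min(a, c), max(a, c))
        if gained in loss_rels:
            continue  # already bonded: not the exchanging diagonal
        if gained not in cur.relations:
            continue
        perimeter = [(a, b), (b, c), (c, d), (d, a)]
        norm = {(min(p), max(p)) for p in perimeter}
        if not (norm <= cur.relations and norm <= loss_rels):
            continue
        return T1Event(
            cells=(a, b, c, d),
            lost_pair=cand.pair,
            gained_pair=gained,
            t_start=cand.t_loss,
            t_end=cur.t,
        )
    return None


def cell_centers(state: MonolayerState, params: SimulationParams,
                 ) -> np.ndarray:
    """B-weighted periodic centroids of all cells, shape (N, 2)."""
    B = indicator_B(state.phi)
    return np.stack([periodic_centroid(B[i], params.L)
                     for i in range(state.n_cells)])


def _weiszfeld_torus(pts: np.ndarray, x0: np.ndarray, L: float,
                     tol: float, max_iter: int) -> np.ndarray:
    """Weiszfeld iteration in the torus metric: at each step the points
    are taken in their minimal images relative to the current iterate."""
    x = x0.copy()
    for _ in range(max_iter):
        delta = torus_delta(pts, x, L)
        d = np.linalg.norm(delta, axis=1)
        at_point = d < tol
        if at_point.any():
            # Vardi-Zhang correction when the iterate lands on a data
            # point: keep it if its unit-gradient pull is subcritical
            y = x + delta[at_point][0]
            rest = torus_delta(pts[~at_point], y, L)
            if len(rest) == 0:
                return wrap_point(y, L)
            r = np.linalg.norm(rest, axis=1)
            grad = (rest / r[:, None]).sum(axis=0)
            gn = np.linalg.norm(grad)
            mult = int(at_point.sum())
            if gn <= mult:
                return wrap_point(y, L)
            x = y + grad / gn * tol * 10
            continue
        w = 1.0 / d
        step = (delta * w[:, None]).sum(axis=0) / w.sum()
        x = x + step
        if np.linalg.norm(step) < tol:
            break
    return wrap_point(x, L)


def geometric_median(points: np.ndarray, L: float, tol_frac: float = 1e-8,
                     max_iter: int = 500) -> np.ndarray:
    """Geometric median of points under the torus metric.

    The objective can have several local minima when the points straddle
    the periodic seams, so the Weiszfeld iteration is restarted from each
    data point and from the circular mean, keeping the best candidate.
    """
    pts = np.asarray(points, float)
    tol = tol_frac * L
    # circular-mean start
    ang = pts / L * (2 * np.pi)
    mean = np.arctan2(np.sin(ang).mean(axis=0),
                      np.cos(ang).mean(axis=0)) % (2 * np.pi) / (
        2 * np.pi) * L
    starts = [mean] + [p.copy() for p in pts]
    # coarse scan to pick the right periodic chart when points straddle
    # several seams (the objective can then have distant local minima)
    m = 16
    xs = (np.arange(m) + 0.5) * (L / m)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    totals = np.zeros(len(grid))
    for p in pts:
        totals += np.linalg.norm(torus_delta(grid, p, L), axis=1)
    starts.append(grid[np.argmin(totals)])
    best, best_val = None, np.inf
    for x0 in starts:
        cand = _weiszfeld_torus(pts, np.asarray(x0, float), L, tol,
                                max_iter)
        val = float(np.linalg.norm(torus_delta(pts, cand, L),
                                   axis=1).sum())
        if val < best_val - 1e-15:
            best, best_val = cand, val
    return best


def epicenter(event: T1Event, state_mid: MonolayerState,
              params: SimulationParams) -> np.ndarray:
    """Epicenter of an event: geometric median (torus metric) of the four
    participating cell centres at the snapshot nearest the temporal
    midpoint of the event."""
    centers = cell_centers(state_mid, params)[list(event.cells)]
    return geometric_median(centers, params.L)
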