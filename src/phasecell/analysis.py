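"""High-level T1 study workflow: run an ensemble of desk-scale active
monolayers, detect and annotate neighbour exchanges, and pool the
event-aligned statistics across runs (duration statistics in the
reference analyses are likewise pooled over several simulations)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Simulation, SimulationResult
from .initial import init_voronoi_monolayer
from .params import SimulationParams, desk_params
from .stats import (DurationStats, EventProfile, _aligned_profile,
                    annotate_events, coarse_energy_series,
                    compute_observables, duration_stats,
                    duration_vs_max_energy, gap_fraction, sample_field)
from .topology import contact_graph, detect_t1

__all__ = ["T1Study", "run_t1_study"]


@dataclass
class T1Study:
    """Pooled results of an ensemble of monolayer runs."""

    params: SimulationParams
    seeds: list
    results: list          # per-run SimulationResult
    graphs: list           # per-run list[ContactGraph]
    coarse_fields: list    # per-run (n_saves, n, n)
    observables: list      # per-run DataFrame
    events: list           # all events; each tagged with .run_index
    energy_profile: EventProfile | None
    shape_profile: EventProfile | None
    speed_profile: EventProfile | None
    durations: DurationStats | None
    duration_energy: pd.DataFrame
    spearman: float
    initial_gap_fraction: float

    @property
    def n_events(self) -> int:
        return len(self.events)


def _pooled_energy_profile(events, study_fields, study_times, params,
                           window):
    idx_maps = [
        {round(t / params.tau_save): k for k, t in enumerate(times)}
        for times in study_times
    ]

    def value_at(ev, t):
        run = ev.run_index
        k = idx_maps[run].get(round(t / params.tau_save))
        if k is None:
            return None
        return sample_field(study_fields[run][k], ev.epicenter, params.L)

    times = np.asarray(study_times[0])
    baseline = float(np.mean([f.mean() for fields in study_fields
                              for f in fields]))
    return _aligned_profile(events, value_at, times, params, window,
                            baseline)


def _pooled_cell_profile(events, pivots, params, window, baseline):
    def value_at(ev, t):
        piv = pivots[ev.run_index]
        key = round(t / params.tau_save) * params.tau_save
        try:
            row = piv.loc[key]
        except KeyError:
            return None
        val = row[list(ev.cells)].mean()
        return float(val)

    times = pivots[0].index.to_numpy()
    return _aligned_profile(events, value_at, times, params, window,
                            baseline)


def run_t1_study(seed: int, n_runs: int = 3,
                 params: SimulationParams | None = None,
                 window: float = 20.0, collect_observables: bool = True,
                 ) -> T1Study:
    """Run ``n_runs`` independent desk-scale monolayers and pool the T1
    statistics.

    ``seed`` controls every source of randomness; run k uses
    ``seed + 1000 k`` for both the initial condition and the propulsion
    noise.
    """
    if params is None:
        params = desk_params()
    seeds = [int(seed) + 1000 * k for k in range(n_runs)]
    results, all_graphs, all_fields, all_obs = [], [], [], []
    events = []
    gap0 = []
    for k, s in enumerate(seeds):
        p = params.replace(seed=s)
        rng = np.random.default_rng(s)
        state = init_voronoi_monolayer(p, rng)
        gap0.append(gap_fraction(state, p))
        sim = Simulation(p, state, seed=s)
        result = sim.run()
        graphs = [contact_graph(snap, p) for snap in result.snapshots]
        fields = coarse_energy_series(result.snapshots, p)
        run_events = detect_t1(graphs)
        annotate_events(run_events, result, coarse_fields=fields)
        for ev in run_events:
            ev.run_index = k
        results.append(result)
        all_graphs.append(graphs)
        all_fields.append(fields)
        events.extend(run_events)
        if collect_observables:
            all_obs.append(compute_observables(result.snapshots,
                                               result.times, p))

    energy_profile = shape_profile = speed_profile = None
    durations = None
    table = pd.DataFrame()
    rho = float("nan")
    if events:
        study_times = [r.times for r in results]
        energy_profile = _pooled_energy_profile(events, all_fields,
                                                study_times, params,
                                                window)
        durations = duration_stats([ev.duration for ev in events])
        table, rho = duration_vs_max_energy(events)
        if collect_observables:
            piv_shape = [o.pivot_table(index="t", columns="cell",
                                       values="shape_index")
                         for o in all_obs]
            piv_speed = [o.pivot_table(index="t", columns="cell",
                                       values="speed") for o in all_obs]
            base_shape = float(np.mean([p.stack().mean()
                                        for p in piv_shape]))
            base_speed = float(np.mean([p.stack().mean()
                                        for p in piv_speed]))
            shape_profile = _pooled_cell_profile(events, piv_shape,
                                                 params, window,
                                                 base_shape)
            speed_profile = _pooled_cell_profile(events, piv_speed,
                                                 params, window,
                                                 base_speed)
    return T1Study(
        params=params, seeds=seeds, results=results, graphs=all_graphs,
        coarse_fields=all_fields, observables=all_obs, events=events,
        energy_profile=energy_profile, shape_profile=shape_profile,
        speed_profile=speed_profile, durations=durations,
        duration_energy=table, spearman=rho,
        initial_gap_fraction=float(np.mean(gap0)),
    )
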