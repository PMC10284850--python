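"""Snapshot persistence (HDF5) and run outputs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .params import SimulationParams
from .state import MonolayerState

__all__ = ["save_state", "load_state", "save_run", "load_run"]


def _write_state(group, state: MonolayerState, rng_states=None):
    group.create_dataset("phi", data=state.phi, compression="gzip",
                         compression_opts=1)
    group.create_dataset("theta", data=state.theta)
    group.attrs["t"] = state.t
    if rng_states is not None:
        group.attrs["rng_states"] = json.dumps(rng_states)


def _read_state(group):
    state = MonolayerState(phi=group["phi"][...], theta=group["theta"][...],
                           t=float(group.attrs["t"]))
    rng_states = None
    if "rng_states" in group.attrs:
        rng_states = json.loads(group.attrs["rng_states"])
    return state, rng_states


def save_state(state: MonolayerState, path, params: SimulationParams,
               rng_states=None) -> None:
    """Bit-faithful dump of one state (fields, angles, time, RNG)."""
    if state.n_cells != params.N or state.grid_n != params.grid_n:
        raise ValueError("state geometry does not match params")
    with h5py.File(path, "w") as fh:
        fh.attrs["params"] = json.dumps(params.to_dict())
        _write_state(fh, state, rng_states)


def load_state(path, params: SimulationParams | None = None):
    """Load a state; returns ``(state, params, rng_states)``.

    When ``params`` is given, its grid must match the stored one.
    """
    with h5py.File(path, "r") as fh:
        stored = SimulationParams(**json.loads(fh.attrs["params"]))
        state, rng_states = _read_state(fh)
    if params is not None:
        if params.grid_n != state.grid_n or params.N != state.n_cells:
            raise ValueError(
                f"stored grid (N={state.n_cells}, n={state.grid_n}) does "
                f"not match requested (N={params.N}, n={params.grid_n})"
            )
    return state, stored, rng_states


def save_run(result, path, rng_states=None, energy_fields=None) -> None:
    """Save a full snapshot sequence, one HDF5 group per save time;
    optionally store the pointwise energy density next to each state."""
    with h5py.File(path, "w") as fh:
        fh.attrs["params"] = json.dumps(result.params.to_dict())
        fh.attrs["times"] = np.asarray(result.times)
        for k, (t, snap) in enumerate(zip(result.times, result.snapshots)):
            grp = fh.create_group(f"save_{t:012.4f}")
            _write_state(grp, snap)
            if energy_fields is not None:
                grp.create_dataset("energy", data=energy_fields[k],
                                   compression="gzip", compression_opts=1)
        if rng_states is not None:
            fh.attrs["rng_states"] = json.dumps(rng_states)


def load_run(path):
    """Inverse of :func:`save_run`; returns a SimulationResult."""
    from .dynamics import SimulationResult

    with h5py.File(path, "r") as fh:
        params = SimulationParams(**json.loads(fh.attrs["params"]))
        times = list(fh.attrs["times"])
        snaps = []
        for t in times:
            state, _ = _read_state(fh[f"save_{t:012.4f}"])
            snaps.append(state)
    return SimulationResult(params, times, snaps)
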