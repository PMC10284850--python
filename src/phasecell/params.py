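"""Model and solver parameters.

The physical constants follow the standard non-dimensionalisation of the
multi-phase field monolayer model: an interface-width parameter ``epsilon``,
a capillary number ``Ca`` weighting the Cahn--Hilliard energy (larger Ca =
more deformable cells), an interaction number ``In`` weighting the pairwise
overlap energy, activity magnitude ``v0``, rotational diffusivity ``D_r``
and an elongation-alignment rate ``alpha``.  The interaction shape parameter
``a`` switches between pure repulsion (a = 1) and repulsion plus adhesion
(a > 1).
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path


class ParameterError(ValueError):
    """Raised when a configuration value violates a model invariant."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


#: Default physical constants of the model (dimensionless units).
PHYSICAL_DEFAULTS = {
    "tau": 0.005,
    "tau_save": 0.5,
    "T": 150.0,
    "L": 100.0,
    "epsilon": 0.15,
    "v0": 0.5,
    "a": 1.5,
    "Ca": 0.2,
    "In": 0.1,
    "D_r": 0.1,
    "alpha": 0.1,
}

_MODES = ("active", "passive_shear")


@dataclass(frozen=True)
class SimulationParams:
    """Complete parameter set for a monolayer simulation.

    Defaults reproduce the reference parameterisation of the model at full
    scale (``N=100`` cells, 2048^2 grid); see :func:`desk_params` for a
    small configuration suited to interactive use and testing.
    """

    tau: float = 0.005          # time step
    tau_save: float = 0.5       # interval between saved snapshots
    T: float = 150.0            # total simulated time
    L: float = 100.0            # periodic domain side length
    epsilon: float = 0.15       # diffuse-interface width scale
    v0: float = 0.5             # self-propulsion speed
    a: float = 1.5              # interaction shape (1 = repulsion only)
    Ca: float = 0.2             # capillary number (deformability)
    In: float = 0.1             # interaction number
    D_r: float = 0.1            # rotational diffusivity
    alpha: float = 0.1          # elongation-alignment rate
    N: int = 100                # number of cells
    grid_n: int = 2048          # grid points per side (power of two)
    seed: int = 0               # RNG seed
    r_avg_frac: float = 0.02    # coarse-graining radius as a fraction of L
    gap_threshold: float = 0.2  # sum_i B(phi_i) cutoff defining a gap
    contact_threshold: float = 0.15  # overlap level defining cell contact
    mode: str = "active"        # "active" or "passive_shear"

    def __post_init__(self):
        validate_params(self)

    # -- derived geometry -------------------------------------------------
    @property
    def dx(self) -> float:
        """Grid spacing L / grid_n."""
        return self.L / self.grid_n

    @property
    def r_avg(self) -> float:
        """Coarse-graining radius in physical units."""
        return self.r_avg_frac * self.L

    @property
    def cell_area(self) -> float:
        """Nominal area per cell assuming full coverage."""
        return self.L**2 / self.N

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.tau))

    @property
    def save_stride(self) -> int:
        return int(round(self.tau_save / self.tau))

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_params(p: SimulationParams) -> None:
    """Check all invariants, raising :class:`ParameterError` on the first
    violated field."""
    if p.tau <= 0:
        raise ParameterError("tau", "time step must be positive")
    if p.tau_save < p.tau:
        raise ParameterError("tau_save", "save interval must be >= tau")
    if p.T < p.tau_save:
        raise ParameterError("T", "total time must be >= tau_save")
    if p.L <= 0:
        raise ParameterError("L", "domain size must be positive")
    if p.epsilon <= 0:
        raise ParameterError("epsilon", "interface width must be positive")
    if p.Ca <= 0:
        raise ParameterError("Ca", "capillary number must be positive")
    if p.In <= 0:
        raise ParameterError("In", "interaction number must be positive")
    if p.a < 1:
        raise ParameterError("a", "interaction shape parameter must be >= 1")
    if p.D_r < 0:
        raise ParameterError("D_r", "rotational diffusivity must be >= 0")
    if p.alpha < 0:
        raise ParameterError("alpha", "alignment rate must be >= 0")
    if p.v0 < 0:
        raise ParameterError("v0", "activity magnitude must be >= 0")
    if p.N < 2:
        raise ParameterError("N", "need at least two cells")
    if p.grid_n < 2 or (p.grid_n & (p.grid_n - 1)) != 0:
        raise ParameterError("grid_n", "grid size must be a power of two")
    if p.L / p.grid_n > p.epsilon / 2 + 1e-12:
        raise ParameterError(
            "grid_n",
            f"grid spacing {p.L / p.grid_n:.4g} exceeds epsilon/2 = "
            f"{p.epsilon / 2:.4g}; the diffuse interface would be "
            "under-resolved",
        )
    if not (0 < p.r_avg_frac < 0.5):
        raise ParameterError("r_avg_frac", "must lie in (0, 0.5)")
    if not (0 < p.gap_threshold < 1):
        raise ParameterError("gap_threshold", "must lie in (0, 1)")
    if not (0 < p.contact_threshold < 1):
        raise ParameterError("contact_threshold", "must lie in (0, 1)")
    if p.mode not in _MODES:
        raise ParameterError("mode", f"must be one of {_MODES}")
    if p.seed < 0:
        raise ParameterError("seed", "seed must be non-negative")


def desk_params(**overrides) -> SimulationParams:
    """Small simulation profile for interactive analysis and tests.

    Keeps every physical constant at its default (including the interface
    width epsilon = 0.15) and shrinks only the geometry: 10 cells in an
    L = 9.5 box on a 128^2 grid, run to T = 60.  Cells then have radius
    about 1.7, i.e. eight interface widths — large enough for compact
    cells to be robustly metastable, which sets the smallest usable cell
    size for this model.
    """
    base = dict(
        L=9.5, grid_n=128, N=10, epsilon=0.15, T=60.0,
    )
    base.update(overrides)
    return SimulationParams(**base)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(SimulationParams)}
_INT_FIELDS = {"N", "grid_n", "seed"}


def load_config(path: str | Path) -> SimulationParams:
    """Load parameters from a flat TOML file.

    Keys are named after the model symbols (``tau``, ``tau_save``, ``T``,
    ``L``, ``epsilon``, ``v0``, ``a``, ``Ca``, ``In``, ``D_r``, ``alpha``)
    plus solver settings.  Omitted keys take the defaults; unknown keys are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ParameterError(sorted(unknown)[0], "unknown configuration key")
    clean = {}
    for key, value in raw.items():
        if key in _INT_FIELDS:
            if not isinstance(value, int) or isinstance(value, bool):
                raise ParameterError(key, "must be an integer")
            clean[key] = value
        elif key == "mode":
            clean[key] = str(value)
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ParameterError(key, "must be a number")
            clean[key] = float(value)
    return SimulationParams(**clean)


def save_config(params: SimulationParams, path: str | Path) -> None:
    """Write parameters as a flat TOML file (lossless round trip)."""
    lines = []
    for key, value in params.to_dict().items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):  # pragma: no cover - no bool fields
            lines.append(f"{key} = {str(value).lower()}")
        elif isinstance(value, int):
            lines.append(f"{key} = {value}")
        else:
            lines.append(f"{key} = {float(value)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunRecord:
    """Provenance metadata for a completed or in-progress run."""

    params: SimulationParams
    snapshot_times: list
    seed: int
    code_version: str = "unknown"

    def __post_init__(self):
        times = self.snapshot_times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("snapshot_times must be strictly increasing")
        for t in times:
            ratio = t / self.params.tau_save
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError(
                    f"snapshot time {t} is not a multiple of tau_save"
                )
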