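"""In-memory simulation state."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MonolayerState:
    """N phase fields on a periodic grid plus per-cell propulsion angles.

    ``phi`` has shape (N, grid_n, grid_n) with axis 1 the x1 direction and
    axis 2 the x2 direction; ``theta`` holds the self-propulsion angles in
    (-pi, pi]; ``t`` is the current simulation time.
    """

    phi: np.ndarray
    theta: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.phi.ndim != 3 or self.phi.shape[1] != self.phi.shape[2]:
            raise ValueError("phi must have shape (N, n, n)")
        if self.theta.shape != (self.phi.shape[0],):
            raise ValueError("theta must have one angle per cell")

    @property
    def n_cells(self) -> int:
        return self.phi.shape[0]

    @property
    def grid_n(self) -> int:
        return self.phi.shape[1]

    def copy(self) -> "MonolayerState":
        return MonolayerState(self.phi.copy(), self.theta.copy(), self.t)
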