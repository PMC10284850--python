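"""Time integration of the conserved phase-field dynamics

    d_t phi_i + v_i . grad phi_i = Lap( dF/dphi_i )

with either active self-propulsion, v_i = v0 B(phi_i) e_i(theta_i), or a
passive shear advection of magnitude 0.5|x1 - L/2| along x2.  The
propulsion angle theta_i follows an Euler--Maruyama step of

    d theta_i = sqrt(2 D_r) dW_i + alpha (beta_i - theta_i) dt

where beta_i is the representative of the cell's elongation axis closest
to theta_i.

The stiff linear Cahn--Hilliard operator is treated implicitly in Fourier
space on the uniform periodic grid; the cubic, interaction and advection
terms are explicit with a stabilising split constant, which allows the
default time step at the default grids.  The explicit divergence and the
advection are evaluated with conservative centred differences (the active
advection as v0 e_i . grad G(phi) with G' = B), whose periodic sums
telescope exactly, so per-cell mass is conserved to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grid import grid_coords, wavenumbers, wrap_angle
from ._kernels import explicit_rhs, shape_components_fd
from .energy import indicator_B
from .params import SimulationParams
from .state import MonolayerState

__all__ = [
    "ShapeTensor", "shape_tensor", "select_beta", "update_orientation",
    "advection_velocity", "Simulation", "SimulationResult", "simulate",
]

#: Relative eigenvalue below which a cell counts as isotropic (no
#: well-defined elongation axis, hence no alignment torque).
ISOTROPY_TOL = 1e-12


@dataclass(frozen=True)
class ShapeTensor:
    """Symmetric traceless shape deformation tensor of one cell.

    S = [[S0, S1], [S1, -S0]] with
    S0 = (1/8) ∫ [(d phi/dy)^2 - (d phi/dx)^2] dx and
    S1 = -(1/4) ∫ [(d phi/dx)(d phi/dy)] dx.
    Eigenvalues are ±lambda_plus; the principal axis angle is
    0.5*atan2(S1, S0) (equivalent to the eigenvector
    ((S0 + lambda_plus)/S1, 1) when S1 != 0).
    """

    S0: float
    S1: float
    isotropic: bool

    @property
    def lam_plus(self) -> float:
        return float(np.hypot(self.S0, self.S1))

    @property
    def angle(self) -> float:
        """Elongation-axis angle in (-pi/2, pi/2], defined modulo pi."""
        return 0.5 * float(np.arctan2(self.S1, self.S0))

    @property
    def eta_plus(self) -> np.ndarray:
        """Unnormalised principal eigenvector."""
        return np.array([np.cos(self.angle), np.sin(self.angle)])

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.S0, self.S1], [self.S1, -self.S0]])


def shape_tensor(phi_i: np.ndarray, params: SimulationParams,
                 method: str = "spectral") -> ShapeTensor:
    """Shape deformation tensor of one phase field."""
    S0, S1 = _shape_components(phi_i[None], params, method)
    lam = float(np.hypot(S0[0], S1[0]))
    area = float(indicator_B(phi_i).sum()) * params.dx**2
    return ShapeTensor(float(S0[0]), float(S1[0]),
                       isotropic=lam < ISOTROPY_TOL * max(area, 1.0))


def _shape_components(phi: np.ndarray, params: SimulationParams,
                      method: str = "fd"):
    """Vectorised (S0, S1) for a stack of fields (N, n, n)."""
    if method == "spectral":
        from ._grid import spectral_gradient
        gx, gy = spectral_gradient(phi, params.L)
        da = params.dx**2
        S0 = (gy**2 - gx**2).sum(axis=(-2, -1)) * (da / 8.0)
        S1 = -(gx * gy).sum(axis=(-2, -1)) * (da / 4.0)
        return S0, S1
    return shape_components_fd(phi, params.dx)


def select_beta(theta, axis_angle, rule: str = "nearest"):
    """Representative of the (nematic) elongation axis used as the
    alignment target.

    ``rule="nearest"`` returns whichever of {axis_angle, axis_angle + pi}
    is within pi/2 of theta.  ``rule="literal"`` applies the sign form
    beta = ±arg(eta+) keyed on the sign of e.eta+ instead.
    """
    theta = np.asarray(theta, float)
    psi = np.asarray(axis_angle, float)
    if rule == "nearest":
        d = wrap_angle(psi - theta)
        d = np.where(np.abs(d) > np.pi / 2, wrap_angle(d + np.pi), d)
        return wrap_angle(theta + d)
    if rule == "literal":
        e_dot = np.cos(theta) * np.cos(psi) + np.sin(theta) * np.sin(psi)
        return wrap_angle(np.where(e_dot >= 0, psi, -psi))
    raise ValueError(f"unknown rule {rule!r}")


def update_orientation(theta, beta, params: SimulationParams,
                       gaussian_increment):
    """One Euler--Maruyama step of the propulsion-angle SDE.

    ``gaussian_increment`` is the Wiener increment, Normal(0, tau).
    """
    drift = params.alpha * wrap_angle(np.asarray(beta) - np.asarray(theta))
    return wrap_angle(
        theta + drift * params.tau
        + np.sqrt(2.0 * params.D_r) * np.asarray(gaussian_increment)
    )


def advection_velocity(state: MonolayerState, params: SimulationParams,
                       i: int):
    """Pointwise advection velocity (vx, vy) of cell i on the grid."""
    if params.mode == "active":
        mag = params.v0 * indicator_B(state.phi[i])
        return (mag * np.cos(state.theta[i]), mag * np.sin(state.theta[i]))
    x1, _ = grid_coords(params.grid_n, params.L)
    speed = 0.5 * np.abs(x1 - params.L / 2)
    zeros = np.zeros((params.grid_n, params.grid_n))
    return (zeros, np.broadcast_to(speed, zeros.shape).copy())


@dataclass
class SimulationResult:
    """Snapshots collected at every save interval, including t=0."""

    params: SimulationParams
    times: list
    snapshots: list  # list[MonolayerState]

    def __iter__(self):
        return iter(self.snapshots)


class Simulation:
    """Semi-implicit Fourier-spectral integrator for a cell monolayer.

    Holds the state, the per-cell RNG substreams (split from one seed by
    cell index, so trajectories are independent of iteration order), and
    the cached spectral operators.
    """

    def __init__(self, params: SimulationParams, state: MonolayerState,
                 seed: int | None = None, rng_states: list | None = None,
                 static_phi: np.ndarray | None = None):
        if state.n_cells != params.N or state.grid_n != params.grid_n:
            raise ValueError("state geometry does not match params")
        self.params = params
        self.state = state
        if seed is None:
            seed = params.seed
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        self.rngs = [np.random.Generator(np.random.PCG64(s))
                     for s in ss.spawn(params.N)]
        if rng_states is not None:
            for rng, st in zip(self.rngs, rng_states):
                rng.bit_generator.state = st

        n, L, tau = params.grid_n, params.L, params.tau
        kx, ky = wavenumbers(n, L)
        self._k2 = kx**2 + ky**2
        # Eyre-type stabilising split constant: bounds the stiffness of
        # the explicit bulk term (phi^3 - phi)/(Ca*eps) plus the presence-
        # localised interaction's curvature (about 6 in w units).
        self.sigma_stab = (2.0 / (params.Ca * params.epsilon)
                           + 6.0 / params.In)
        self._denom = (1.0 + tau * (params.epsilon / params.Ca) * self._k2**2
                       + tau * self.sigma_stab * self._k2)
        # optional frozen background field (e.g. a confinement ring):
        # enters the interaction sums of every cell but never evolves
        if static_phi is None:
            self._w_static = np.zeros(n * n)
            self._B_static = np.zeros(n * n)
        else:
            from .energy import clamped_interaction_terms

            Bs, ws, _, _ = clamped_interaction_terms(
                np.asarray(static_phi)[None], params.a)
            self._w_static = np.ascontiguousarray(ws[0].ravel())
            self._B_static = np.ascontiguousarray(Bs[0].ravel())
        self._phi_hat = np.fft.rfft2(state.phi)
        x1, _ = grid_coords(n, L)
        self._shear_speed = np.ascontiguousarray(
            0.5 * np.abs(x1[:, 0] - L / 2))
        self._zero_shear = np.zeros(n)
        self._step_count = 0

    # -- single step ------------------------------------------------------
    def step(self) -> None:
        p = self.params
        phi = self.state.phi
        tau = p.tau

        active = p.mode == "active"
        if active:
            ex = p.v0 * np.cos(self.state.theta)
            ey = p.v0 * np.sin(self.state.theta)
            shear = self._zero_shear
        else:
            ex = ey = np.zeros(p.N)
            shear = self._shear_speed
        # explicit terms (advection in conservative form: the active term
        # is v0 e_i . grad G(phi_i) with G' = B, so mass is exact)
        E = explicit_rhs(phi, p.a, 1.0 / (p.Ca * p.epsilon), 1.0 / p.In,
                         self.sigma_stab, p.dx, ex, ey, shear, active,
                         self._w_static, self._B_static)
        self._phi_hat = (self._phi_hat + tau * np.fft.rfft2(E)) \
            / self._denom
        self.state.phi = np.fft.irfft2(self._phi_hat, s=phi.shape[-2:])

        if p.mode == "active":
            self._update_angles()
        self.state.t += tau
        self._step_count += 1
        if self._step_count % 200 == 0:
            m = np.abs(self.state.phi).max()
            if not np.isfinite(m) or m > 5.0:
                raise RuntimeError(
                    f"phase fields diverged at t={self.state.t:.3f} "
                    f"(|phi|max={m:.3g}); the time step tau={tau} is too "
                    "large for this grid"
                )

    def _update_angles(self) -> None:
        p = self.params
        S0, S1 = _shape_components(self.state.phi, p, method="fd")
        lam = np.hypot(S0, S1)
        psi = 0.5 * np.arctan2(S1, S0)
        iso = lam < ISOTROPY_TOL * max(p.cell_area, 1.0)
        beta = select_beta(self.state.theta, psi)
        beta = np.where(iso, self.state.theta, beta)
        incr = np.array([rng.normal(0.0, np.sqrt(p.tau))
                         for rng in self.rngs])
        self.state.theta = update_orientation(self.state.theta, beta,
                                              p, incr)

    # -- runs -------------------------------------------------------------
    def run(self, t_end: float | None = None, collect: bool = True,
            callback=None) -> SimulationResult:
        """Advance until ``t_end`` (default params.T), saving a snapshot
        every tau_save.  ``callback(state)`` runs at each save."""
        p = self.params
        if t_end is None:
            t_end = p.T
        times, snaps = [], []

        def _save():
            times.append(self.state.t)
            if collect:
                snaps.append(self.state.copy())
            if callback is not None:
                callback(self.state)

        _save()
        stride = p.save_stride
        n_steps = int(round((t_end - self.state.t) / p.tau))
        for k in range(1, n_steps + 1):
            self.step()
            if k % stride == 0:
                # snap time to the save lattice to avoid float drift
                self.state.t = round(self.state.t / p.tau_save) * p.tau_save
                _save()
        return SimulationResult(p, times, snaps)

    @property
    def rng_states(self) -> list:
        return [rng.bit_generator.state for rng in self.rngs]


def simulate(params: SimulationParams, state: MonolayerState | None = None,
             seed: int | None = None, t_end: float | None = None,
             callback=None, collect: bool = True) -> SimulationResult:
    """Convenience wrapper: build (or take) an initial state and run."""
    if state is None:
        from .initial import init_voronoi_monolayer
        rng = np.random.default_rng(params.seed if seed is None else seed)
        state = init_voronoi_monolayer(params, rng)
    sim = Simulation(params, state, seed=seed)
    return sim.run(t_end=t_end, callback=callback, collect=collect)
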