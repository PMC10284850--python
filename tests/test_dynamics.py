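"""Shape tensor, orientation dynamics, advection and the conservation /
dissipation contracts of the time stepper."""

import numpy as np
import pytest

import phasecell as pc
from phasecell._grid import wrap_angle
from phasecell.dynamics import _shape_components


def ellipse_field(params, semi_x, semi_y, angle=0.0, center=None):
    """tanh profile whose zero level set is an ellipse."""
    from phasecell._grid import grid_coords, torus_delta

    L = params.L
    if center is None:
        center = (L / 2, L / 2)
    x1, x2 = grid_coords(params.grid_n, L)
    dx1 = torus_delta(x1, center[0], L)
    dx2 = torus_delta(x2, center[1], L)
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx1 + s * dx2
    v = -s * dx1 + c * dx2
    rho = np.sqrt((u / semi_x) ** 2 + (v / semi_y) ** 2)
    scale = np.sqrt(semi_x * semi_y)
    return np.tanh((1 - rho) * scale / (np.sqrt(2) * params.epsilon))


class TestShapeTensor:
    def test_disk_is_isotropic(self, tiny_params):
        p = tiny_params
        phi = pc.disk_phase_field((p.L / 2, p.L / 2), 1.2, p)
        st = pc.shape_tensor(phi, p)
        area = np.pi * 1.2**2
        assert abs(st.S0) < 1e-6 * area
        assert abs(st.S1) < 1e-6 * area

    def test_elongation_axis_of_vertical_ellipse(self):
        p = pc.SimulationParams(L=9.6, grid_n=128, N=2, epsilon=0.15,
                                T=1.0)
        phi = ellipse_field(p, 1.0, 2.0)  # major axis along x2
        st = pc.shape_tensor(phi, p)
        assert not st.isotropic
        assert abs(wrap_angle(2 * (st.angle - np.pi / 2))) < np.deg2rad(2)

    def test_rotation_equivariance(self):
        p = pc.SimulationParams(L=9.6, grid_n=128, N=2, epsilon=0.15,
                                T=1.0)
        psi = 0.35
        st0 = pc.shape_tensor(ellipse_field(p, 1.0, 2.0), p)
        st1 = pc.shape_tensor(ellipse_field(p, 1.0, 2.0, angle=psi), p)
        dd = wrap_angle(2 * (st1.angle - st0.angle)) / 2  # modulo pi
        assert dd == pytest.approx(psi, abs=np.deg2rad(1))

    def test_eigenpair_closed_form(self):
        st = pc.ShapeTensor(S0=0.3, S1=-0.4, isotropic=False)
        assert st.lam_plus == pytest.approx(0.5)
        v = st.eta_plus
        assert np.allclose(st.matrix @ v, st.lam_plus * v, atol=1e-12)


class TestBetaSelection:
    def test_same_halfplane(self):
        assert pc.select_beta(0.1, 0.2) == pytest.approx(0.2)

    def test_antipodal_representative(self):
        beta = pc.select_beta(np.pi - 0.1, 0.0)
        assert abs(wrap_angle(beta - np.pi)) < 1e-12

    def test_nearest_within_quarter_turn(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 500)
        psi = rng.uniform(-np.pi, np.pi, 500)
        beta = pc.select_beta(theta, psi)
        assert np.all(np.abs(wrap_angle(beta - theta)) <= np.pi / 2 + 1e-9)
        # beta is parallel to the axis
        assert np.all(np.abs(wrap_angle(2 * (beta - psi))) < 1e-9)

    def test_literal_sign_rule(self):
        # e.eta+ < 0 branch reflects the angle instead of flipping it
        beta = pc.select_beta(np.pi - 0.1, 0.3, rule="literal")
        assert beta == pytest.approx(-0.3)


class TestOrientationUpdate:
    def test_fixed_point_without_noise(self, tiny_params):
        p = tiny_params.replace(D_r=0.0)
        assert pc.update_orientation(0.7, 0.7, p, 0.0) == pytest.approx(0.7)

    def test_exponential_relaxation_to_axis(self):
        p = pc.SimulationParams(L=4.8, grid_n=64, N=2, epsilon=0.15,
                                T=1.0, D_r=0.0, alpha=0.5, tau=0.01)
        theta, beta = 0.9, 0.1
        t_total = 2.0
        n = int(t_total / p.tau)
        for _ in range(n):
            theta = pc.update_orientation(theta, beta, p, 0.0)
        expected = beta + (0.9 - beta) * np.exp(-p.alpha * t_total)
        assert theta == pytest.approx(expected, abs=2 * p.tau)

    def test_wiener_variance_growth(self, rng):
        p = pc.SimulationParams(L=4.8, grid_n=64, N=2, epsilon=0.15,
                                T=1.0, alpha=0.0, D_r=0.2, tau=0.01)
        n_paths, n_steps = 20000, 50
        theta = np.zeros(n_paths)
        total = np.zeros(n_paths)  # unwrapped displacement
        for _ in range(n_steps):
            incr = rng.normal(0.0, np.sqrt(p.tau), n_paths)
            new = pc.update_orientation(theta, theta, p, incr)
            total += wrap_angle(new - theta)
            theta = new
        t = n_steps * p.tau
        assert total.var() == pytest.approx(2 * p.D_r * t, rel=0.05)


class TestAdvection:
    def test_active_velocity_profile(self, tiny_params):
        p = tiny_params
        phi = np.stack([pc.disk_phase_field((p.L / 2, p.L / 2), 1.2, p),
                        -np.ones((p.grid_n, p.grid_n))])
        state = pc.MonolayerState(phi, np.array([0.3, 0.0]))
        vx, vy = pc.advection_velocity(state, p, 0)
        speed = np.hypot(vx, vy)
        interior = phi[0] > 0.999
        exterior = phi[0] < -0.999
        assert np.allclose(speed[interior], p.v0, atol=1e-3)
        assert np.allclose(speed[exterior], 0.0, atol=1e-3)

    def test_passive_shear_profile(self, tiny_params):
        p = tiny_params.replace(mode="passive_shear")
        phi = np.stack([pc.disk_phase_field((p.L / 2, p.L / 2), 1.0, p),
                        -np.ones((p.grid_n, p.grid_n))])
        state = pc.MonolayerState(phi, np.zeros(2))
        vx, vy = pc.advection_velocity(state, p, 0)
        mid = p.grid_n // 2
        assert np.allclose(vx, 0.0)
        assert vy[mid, 0] == pytest.approx(0.0, abs=1e-12)
        assert vy[0, 0] == pytest.approx(p.L / 4)


def _relaxing_pair(p):
    """One live elliptical cell plus an inert exterior partner (phi = -1
    everywhere), the single-cell relaxation scenario."""
    phi = np.stack([
        ellipse_field(p, 1.0, 1.4),
        -np.ones((p.grid_n, p.grid_n)),
    ])
    return pc.MonolayerState(phi, np.zeros(2))


class TestStepper:
    def test_energy_dissipates_without_activity(self, tiny_params):
        p = tiny_params.replace(v0=0.0)
        sim = pc.Simulation(p, _relaxing_pair(p))
        # let the profile settle through the first save interval, then
        # demand per-step monotone decrease
        for _ in range(p.save_stride):
            sim.step()
        # monotone up to the first-order splitting error of the scheme
        F = F0 = pc.free_energy(sim.state.phi, p)
        for _ in range(300):
            sim.step()
            F_new = pc.free_energy(sim.state.phi, p)
            assert F_new <= F + 1e-5 * max(abs(F), 1.0)
            F = F_new
        assert F < F0

    def test_per_cell_mass_conserved(self, tiny_params):
        p = tiny_params
        sim = pc.Simulation(p, _relaxing_pair(p))
        m0 = sim.state.phi.sum(axis=(1, 2))
        for _ in range(1000):
            sim.step()
        m1 = sim.state.phi.sum(axis=(1, 2))
        assert np.abs((m1 - m0) / m0).max() < 1e-6

    def test_translation_equivariance(self, tiny_params):
        # alpha=0 avoids the nematic branch choice, which is genuinely
        # discontinuous when theta sits exactly a quarter turn from the
        # elongation axis
        p = tiny_params.replace(alpha=0.0)
        state = _relaxing_pair(p)
        shifted = pc.MonolayerState(np.roll(state.phi, (7, -3), (1, 2)),
                                    state.theta.copy())
        sim_a = pc.Simulation(p, state, seed=3)
        sim_b = pc.Simulation(p, shifted, seed=3)
        for _ in range(20):
            sim_a.step()
            sim_b.step()
        assert np.allclose(np.roll(sim_a.state.phi, (7, -3), (1, 2)),
                           sim_b.state.phi, atol=1e-10)
        assert np.allclose(sim_a.state.theta, sim_b.state.theta)

    def test_first_order_time_convergence(self, tiny_params):
        p = tiny_params.replace(v0=0.0, T=0.5)
        F_end = {}
        for tau in (p.tau, p.tau / 2):
            sim = pc.Simulation(p.replace(tau=tau), _relaxing_pair(p))
            sim.run(t_end=0.5, collect=False)
            F_end[tau] = pc.free_energy(sim.state.phi, p)
        rel = abs(F_end[p.tau] - F_end[p.tau / 2]) / abs(F_end[p.tau / 2])
        assert rel < 0.01

    def test_elliptical_cell_relaxes_toward_disk(self, tiny_params):
        p = tiny_params.replace(v0=0.0)
        sim = pc.Simulation(p, _relaxing_pair(p))
        lams = []
        for _ in range(10):
            for _ in range(40):
                sim.step()
            S0, S1 = _shape_components(sim.state.phi[:1], p, method="fd")
            lams.append(float(np.hypot(S0[0], S1[0])))
        assert all(b <= a + 1e-9 for a, b in zip(lams, lams[1:]))

    def test_blowup_detection(self, tiny_params):
        p = tiny_params
        sim = pc.Simulation(p, _relaxing_pair(p))
        sim.state.phi[0, 0, 0] = np.nan
        sim._phi_hat = np.fft.rfft2(sim.state.phi)
        with pytest.raises(RuntimeError, match="diverged"):
            for _ in range(400):
                sim.step()
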