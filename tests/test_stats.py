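"""Coarse-graining, event-aligned profile machinery, duration statistics,
shape index, gap fraction, tissue flow and event chaining."""

import numpy as np
import pandas as pd
import pytest

import phasecell as pc
from phasecell.stats import sample_field
from phasecell.topology import T1Event


class TestCoarseGrain:
    def test_uniform_field_unchanged(self, tiny_params):
        p = tiny_params
        f = np.full((p.grid_n, p.grid_n), 3.7)
        g = pc.coarse_grain(f, p, r_avg=0.3)
        assert np.allclose(g, 3.7)

    def test_point_mass_spreads_to_disk(self, tiny_params):
        p = tiny_params
        n = p.grid_n
        f = np.zeros((n, n))
        f[20, 30] = 5.0
        r = 0.35
        g = pc.coarse_grain(f, p, r_avg=r)
        # direct-summation oracle
        iy, ix = np.meshgrid(np.arange(n), np.arange(n))
        d2 = (np.minimum(np.abs(ix - 20), n - np.abs(ix - 20)) ** 2
              + np.minimum(np.abs(iy - 30), n - np.abs(iy - 30)) ** 2)
        disk = d2 * p.dx**2 < r**2
        expected = np.where(disk, 5.0 / disk.sum(), 0.0)
        assert np.allclose(g, expected, atol=1e-10)
        assert g.mean() == pytest.approx(f.mean(), rel=1e-12)

    def test_corner_mass_wraps_all_four_corners(self, tiny_params):
        p = tiny_params
        n = p.grid_n
        f = np.zeros((n, n))
        f[0, 0] = 1.0
        g = pc.coarse_grain(f, p, r_avg=0.3)
        assert g[0, 0] > 0
        assert g[-1, -1] > 0 and g[0, -1] > 0 and g[-1, 0] > 0

    def test_mean_preserved_on_random_field(self, tiny_params, rng):
        p = tiny_params
        f = rng.random((p.grid_n, p.grid_n))
        g = pc.coarse_grain(f, p, r_avg=0.4)
        assert g.mean() == pytest.approx(f.mean(), rel=1e-12)

    def test_subgrid_radius_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            pc.coarse_grain(np.zeros((64, 64)), tiny_params,
                            r_avg=0.5 * tiny_params.dx)


def _uniform_fields(values, n=16):
    """Coarse-field stack where every field is spatially uniform, so the
    profile machinery samples a scripted time series exactly."""
    return np.array([np.full((n, n), v) for v in values])


class TestEventProfiles:
    def make(self, values, times, events, params, window=5.0):
        fields = _uniform_fields(values)
        return pc.event_energy_profile(events, fields, times, params,
                                       window=window)

    def test_triangular_series_reproduced_exactly(self, tiny_params):
        p = tiny_params  # tau_save = 0.5
        times = np.arange(0, 21) * p.tau_save
        peak_k = 10
        values = 1.0 + np.minimum(np.arange(21), 20 - np.arange(21)) * 0.1
        ev = T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                     gained_pair=(0, 2), t_start=times[peak_k - 2],
                     t_end=times[peak_k + 2],
                     epicenter=np.array([1.0, 1.0]))
        prof = self.make(values, times, [ev], p, window=2.0)
        # pre branch: t_rel<0 relative to t_start
        for t_rel, mean in zip(prof.t_rel, prof.mean):
            if t_rel < 0:
                k = peak_k - 2 + int(round(t_rel / p.tau_save))
            else:
                k = peak_k + 2 + int(round(t_rel / p.tau_save))
            assert mean == pytest.approx(values[k])
        assert prof.start_value == pytest.approx(values[peak_k - 2])
        assert prof.end_value == pytest.approx(values[peak_k + 2])
        # during-event 21-point resample of a triangle is exact
        frac = prof.during_frac / 100.0
        expect = np.interp(frac * 4, np.arange(5),
                           values[peak_k - 2:peak_k + 3])
        assert np.allclose(prof.during_mean, expect)
        assert prof.baseline == pytest.approx(np.mean(values))

    def test_identical_events_have_zero_std(self, tiny_params):
        p = tiny_params
        times = np.arange(0, 41) * p.tau_save
        values = np.sin(times) + 2.0
        events = []
        for _ in range(4):
            events.append(T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                                  gained_pair=(0, 2), t_start=8.0,
                                  t_end=10.0,
                                  epicenter=np.array([0.5, 0.5])))
        prof = self.make(values, times, events, p, window=3.0)
        assert np.allclose(prof.std, 0.0, atol=1e-12)
        assert np.all(prof.n_events == 4)

    def test_window_clipped_at_run_edges(self, tiny_params):
        p = tiny_params
        times = np.arange(0, 11) * p.tau_save
        values = np.ones(11)
        ev = T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                     gained_pair=(0, 2), t_start=0.5, t_end=1.0,
                     epicenter=np.array([0.5, 0.5]))
        prof = self.make(values, times, [ev], p, window=5.0)
        assert prof.t_rel.min() == pytest.approx(-0.5)

    def test_crossings_and_asymmetry_levels(self, tiny_params):
        p = tiny_params
        # slow decay after the event, fast rise before it
        times = np.arange(0, 41) * p.tau_save
        t_start, t_end = 10.0, 10.5
        values = np.where(times < t_start, 1.0 + np.exp(
            -(t_start - times) / 1.0), 1.0 + np.exp(
            -(times - t_end) / 4.0))
        ev = T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                     gained_pair=(0, 2), t_start=t_start, t_end=t_end,
                     epicenter=np.array([0.5, 0.5]))
        prof = self.make(values, times, [ev], p, window=8.0)
        rise, decay = pc.profile_asymmetry(prof, level_frac=0.25)
        assert rise is not None and decay is not None
        assert decay > rise
        t_pre, t_post = pc.profile_crossings(prof, frac=0.75)
        assert t_pre is not None and t_post is not None
        assert -t_pre < t_post


class TestDurations:
    def test_simple_mean(self):
        ds = pc.duration_stats([2.0, 4.0], min_fit=5)
        assert ds.mean == pytest.approx(3.0)
        assert ds.degenerate

    def test_degenerate_all_equal(self):
        ds = pc.duration_stats([1.5] * 50)
        assert ds.degenerate and ds.fit is None
        assert ds.mean == pytest.approx(1.5)

    def test_gamma_mle_parameter_recovery(self, rng):
        k_true, scale_true = 3.0, 1.2
        sample = rng.gamma(k_true, scale_true, size=2000)
        ds = pc.duration_stats(sample)
        assert ds.fit is not None
        assert ds.fit.shape == pytest.approx(k_true, rel=0.10)
        assert ds.fit.shape * ds.fit.scale == pytest.approx(
            sample.mean(), rel=1e-6)

    def test_duration_energy_perfect_monotone(self):
        events = [T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                          gained_pair=(0, 2), t_start=0.0, t_end=6.0 / e,
                          max_energy=e)
                  for e in (1.0, 2.0, 3.0, 4.0)]
        table, rho = pc.duration_vs_max_energy(events)
        assert rho == pytest.approx(-1.0)
        assert len(table) == 4

    def test_duration_energy_undefined_for_constants(self):
        events = [T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                          gained_pair=(0, 2), t_start=0.0, t_end=1.0,
                          max_energy=2.0) for _ in range(5)]
        _, rho = pc.duration_vs_max_energy(events)
        assert np.isnan(rho)


class TestShapeIndex:
    def params(self):
        return pc.SimulationParams(L=6.0, grid_n=256, N=2, epsilon=0.1,
                                   T=1.0)

    def test_disk_attains_isoperimetric_minimum(self):
        p = self.params()
        phi = pc.disk_phase_field((3.0, 3.0), 1.2, p)
        si = pc.shape_index(phi, p)
        assert si == pytest.approx(2 * np.sqrt(np.pi), rel=0.005)

    def test_regular_pentagon(self):
        p = self.params()
        r = 1.3
        verts = [(r * np.cos(2 * np.pi * k / 5 + np.pi / 2),
                  r * np.sin(2 * np.pi * k / 5 + np.pi / 2))
                 for k in range(5)]
        phi = pc.polygon_phase_field(verts, p)
        assert pc.shape_index(phi, p) == pytest.approx(3.813, rel=0.005)

    def test_square(self):
        p = self.params()
        verts = [(-1, -1), (1, -1), (1, 1), (-1, 1)]
        phi = pc.polygon_phase_field(verts, p)
        assert pc.shape_index(phi, p) == pytest.approx(4.0, rel=0.005)

    def test_periodic_blob_recentred(self):
        p = self.params()
        phi = pc.disk_phase_field((0.1, 5.9), 1.0, p)  # wraps the corner
        si = pc.shape_index(phi, p)
        assert si == pytest.approx(2 * np.sqrt(np.pi), rel=0.005)

    def test_diffuse_perimeter_cross_check(self):
        p = self.params()
        r = 1.2
        phi = pc.disk_phase_field((3.0, 3.0), r, p)
        assert pc.diffuse_perimeter(phi, p) == pytest.approx(
            2 * np.pi * r, rel=0.02)

    def test_degenerate_contour_raises(self):
        p = self.params()
        with pytest.raises(ValueError):
            pc.shape_index(-np.ones((p.grid_n, p.grid_n)), p)


class TestGapFraction:
    def test_fully_covered(self, tiny_params):
        p = tiny_params
        phi = np.stack([np.ones((p.grid_n, p.grid_n)),
                        -np.ones((p.grid_n, p.grid_n))])
        state = pc.MonolayerState(phi, np.zeros(2))
        assert pc.gap_fraction(state, p) == 0.0

    def test_empty_domain(self, tiny_params):
        p = tiny_params
        phi = -np.ones((2, p.grid_n, p.grid_n))
        state = pc.MonolayerState(phi, np.zeros(2))
        assert pc.gap_fraction(state, p) == 1.0

    def test_half_covered(self, tiny_params):
        p = tiny_params
        n = p.grid_n
        phi = -np.ones((2, n, n))
        phi[0, : n // 2, :] = 1.0
        state = pc.MonolayerState(phi, np.zeros(2))
        assert pc.gap_fraction(state, p) == pytest.approx(0.5)


class TestFlowField:
    def test_uniform_translation(self, tiny_params, rng):
        p = tiny_params
        centers = rng.uniform(0, p.L, size=(6, 2))
        vel = np.tile([0.3, -0.1], (6, 1))
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([(i, (i + 1) % 6) for i in range(6)])
        vx, vy, fallback = pc.tissue_flow_field(centers, vel, g, p)
        assert np.allclose(vx, 0.3, atol=1e-8)
        assert np.allclose(vy, -0.1, atol=1e-8)

    def test_outlier_smoothed_by_neighbour_average(self, tiny_params):
        p = tiny_params
        centers = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
        vel = np.array([[0.0, 0.0], [9.0, 0.0], [0.0, 0.0]])
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2)])
        vx, vy, _ = pc.tissue_flow_field(centers, vel, g, p)
        # outlier (9.0) averaged down everywhere by its neighbours
        assert vx.max() <= 4.5 + 1e-9

    def test_needs_three_cells(self, tiny_params):
        import networkx as nx

        with pytest.raises(ValueError):
            pc.tissue_flow_field(np.zeros((2, 2)), np.zeros((2, 2)),
                                 nx.Graph(), tiny_params)


class TestChains:
    def _ev(self, t, x, y):
        return T1Event(cells=(0, 1, 2, 3), lost_pair=(1, 3),
                       gained_pair=(0, 2), t_start=t, t_end=t + 1.0,
                       epicenter=np.array([x, y]))

    def test_colocated_events_chain(self, tiny_params):
        p = tiny_params
        events = [self._ev(0.0, 1.0, 1.0), self._ev(1.0, 1.2, 1.0)]
        chains = pc.chain_candidates(events, r_chain=0.5, dt_chain=3.0,
                                     params=p)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_distant_events_stay_singletons(self, tiny_params):
        p = tiny_params
        events = [self._ev(0.0, 0.5, 0.5), self._ev(1.0, 3.0, 3.0)]
        chains = pc.chain_candidates(events, r_chain=0.5, dt_chain=3.0,
                                     params=p)
        assert len(chains) == 2

    def test_periodic_distance_used(self, tiny_params):
        p = tiny_params
        events = [self._ev(0.0, 0.1, 2.0), self._ev(1.0, p.L - 0.1, 2.0)]
        chains = pc.chain_candidates(events, r_chain=0.5, dt_chain=3.0,
                                     params=p)
        assert len(chains) == 1


def test_sample_field_bilinear_wraps(tiny_params):
    p = tiny_params
    n = p.grid_n
    f = np.zeros((n, n))
    f[0, 0] = 4.0
    # halfway between the last and first grid point along x
    v = sample_field(f, (p.L - p.dx / 2, 0.0), p.L)
    assert v == pytest.approx(2.0)


def test_group_com_trajectory_unwraps(tiny_params):
    p = tiny_params
    t = np.arange(5) * p.tau_save
    # single cell drifting across the periodic seam
    xs = (0.9 * p.L + 0.05 * p.L * np.arange(5)) % p.L
    df = pd.DataFrame({"t": t, "cell": 0, "x": xs, "y": np.full(5, 1.0)})
    traj = pc.group_com_trajectory(df, [0], p)
    steps = np.diff(traj[:, 0])
    assert np.allclose(steps, 0.05 * p.L)
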