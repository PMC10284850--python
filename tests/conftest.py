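import numpy as np
import pytest

import phasecell as pc


@pytest.fixture(scope="session")
def tiny_params():
    """Small two-cell system for fast solver checks."""
    return pc.SimulationParams(L=4.8, grid_n=64, N=2, epsilon=0.15, T=2.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def smooth_field(rng, n, amplitude=0.9, corr=800.0):
    """Random smooth periodic field with |values| <= amplitude."""
    f = rng.normal(size=(n, n))
    fh = np.fft.rfft2(f)
    kx = np.fft.fftfreq(n)[:, None]
    ky = np.fft.rfftfreq(n)[None, :]
    fh *= np.exp(-(kx**2 + ky**2) * corr)
    g = np.fft.irfft2(fh, s=(n, n))
    return amplitude * g / np.abs(g).max()


@pytest.fixture(scope="session")
def fixture_exchange_run():
    """Four-cell diamond fixture driven through exactly one neighbour
    exchange by deterministic propulsion inside the frozen confinement
    ring; shared by the detector and statistics tests."""
    p = pc.SimulationParams(L=12.0, grid_n=256, N=4, epsilon=0.15,
                            T=8.0, mode="active", D_r=0.0, alpha=0.0)
    state = pc.init_t1_fixture(p)
    sim = pc.Simulation(p, state, static_phi=pc.fixture_confinement(p))
    result = sim.run()
    return p, result


@pytest.fixture(scope="session")
def desk_run():
    """Default desk-scale active monolayer run with event detection and
    annotation; the expensive shared input of the statistics tests."""
    p = pc.desk_params(seed=1)
    rng = np.random.default_rng(p.seed)
    state = pc.init_voronoi_monolayer(p, rng)
    sim = pc.Simulation(p, state)
    result = sim.run()
    graphs = [pc.contact_graph(s, p) for s in result.snapshots]
    events = pc.detect_t1(graphs)
    fields = pc.coarse_energy_series(result.snapshots, p)
    pc.annotate_events(events, result, coarse_fields=fields)
    return dict(params=p, result=result, graphs=graphs, events=events,
                fields=fields)
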