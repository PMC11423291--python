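import numpy as np
import pytest

from avalanchekit.raster import SpikeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_raster():
    """Three neurons, hand-placed spikes over one second."""
    return SpikeRaster(
        spike_times=[
            np.array([0.010, 0.030, 0.500]),
            np.array([0.020]),
            np.array([]),
        ],
        duration=1.0,
        frame_interval=0.005,
    )


def make_poisson_raster(n_neurons, duration, rate_hz, rng, positions=False):
    """Independent-Poisson raster used by conservation / property tests."""
    spike_times = []
    for _ in range(n_neurons):
        n_sp = rng.poisson(rate_hz * duration)
        spike_times.append(np.unique(np.sort(rng.uniform(0, duration, n_sp))))
    pos = rng.uniform(0, 1000.0, (n_neurons, 2)) if positions else None
    return SpikeRaster(
        spike_times=spike_times, duration=duration, frame_interval=0.005, positions=pos
    )


@pytest.fixture
def poisson_raster(rng):
    return make_poisson_raster(40, 20.0, 3.0, rng)


def make_bursting_raster(n_neurons=60, n_bursts=12, rng=None):
    """Alternating high/low activity: bursts of ~0.4 s every ~4 s.

    Small synthetic stand-in for a bistable culture recording, used to
    exercise the state-detection and pipeline plumbing quickly.
    """
    rng = rng or np.random.default_rng(7)
    duration = n_bursts * 4.0
    spikes = [[] for _ in range(n_neurons)]
    for b in range(n_bursts):
        t0 = 4.0 * b + 1.0
        for i in range(n_neurons):
            n_sp = rng.poisson(8.0)  # ~20 Hz inside the burst
            spikes[i].extend(rng.uniform(t0, t0 + 0.4, n_sp))
    for i in range(n_neurons):  # sparse background firing (~0.05 Hz)
        spikes[i].extend(rng.uniform(0, duration, rng.poisson(0.05 * duration)))
    return SpikeRaster(
        spike_times=[np.unique(np.sort(s)) for s in spikes],
        duration=duration,
        frame_interval=0.005,
        positions=rng.uniform(0, 500.0, (n_neurons, 2)),
    )


@pytest.fixture(scope="session")
def critical_branching():
    """10^6 critical Galton-Watson avalanches (the mean-field oracle)."""
    from avalanchekit.simulation import branching_process

    aset, capped = branching_process(
        1_000_000, m=1.0, max_generations=10_000, rng_seed=12345
    )
    return aset, capped


@pytest.fixture(scope="session")
def culture_report():
    """Full scaled-down culture simulation and analysis (shared: ~12 min)."""
    from avalanchekit.network import scaled_down_config
    from avalanchekit.pipeline import AnalysisConfig, run_full_analysis

    cfg = AnalysisConfig(
        simulation=scaled_down_config(seed=1, duration_s=600.0),
        patch_radius_um=500.0,
        seed=1,
        label="sim-homogeneous",
    )
    return run_full_analysis(cfg)
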