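import numpy as np
import pytest
from dataclasses import replace

from avalanchekit.network import (
    NeuronParams,
    SimulationConfig,
    SynapseParams,
    apply_variant,
    build_network,
    _polyline_hits_disks,
)
from avalanchekit.simulation import branching_process, simulate, simulate_single_neuron


def small_config(**kw):
    defaults = dict(
        side_length_mm=0.5, density_per_mm2=800.0, duration_s=5.0, seed=3,
        axon_scale_um=200.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestNetworkBuild:
    def test_determinism(self):
        cfg = small_config()
        a = build_network(cfg)
        b = build_network(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(a.indptr, b.indptr)

    def test_inhibitory_fraction(self):
        net = build_network(small_config())
        assert net.ei_label.sum() == round(0.2 * net.n_neurons)

    def test_zero_connection_probability(self):
        net = build_network(small_config(connection_probability=0.0))
        assert net.n_connections == 0

    def test_no_self_connections(self):
        net = build_network(small_config())
        for pre in range(net.n_neurons):
            assert pre not in net.targets[net.indptr[pre]:net.indptr[pre + 1]]

    def test_distant_neurons_never_connect(self):
        # two neurons 10 mm apart with ~120 um axons cannot touch
        cfg = SimulationConfig(
            side_length_mm=12.0, density_per_mm2=2 / 144, duration_s=1.0,
            axon_scale_um=100.0, connection_probability=1.0, seed=0,
        )
        net = build_network(cfg)
        if net.n_neurons == 2:
            d = np.hypot(*(net.positions[0] - net.positions[1]))
            if d > 5000:
                assert net.n_connections == 0

    def test_edges_match_geometric_oracle(self):
        """With acceptance probability 1 the edge set equals the exhaustive
        axon-disk intersection recomputation."""
        cfg = small_config(connection_probability=1.0, keep_axon_geometry=True)
        net = build_network(cfg)
        n = net.n_neurons
        for pre in range(0, n, 7):  # subsample pres to keep the oracle cheap
            pts = net.axon_polylines[pre]
            others = np.array([j for j in range(n) if j != pre])
            hits = _polyline_hits_disks(
                pts, net.positions[others], net.dendrite_radii[others]
            )
            expected = set(others[hits])
            actual = set(net.targets[net.indptr[pre]:net.indptr[pre + 1]])
            assert actual == expected


class TestVariants:
    def test_homogeneous_defaults(self):
        net = build_network(small_config())
        pop = apply_variant(net, small_config())
        assert np.all(pop.v_r == -60.0)
        assert np.all(pop.v_c[pop.neuron_type != 1] == -50.0)

    def test_heterogeneous_population_split(self):
        cfg = small_config(variant="heterogeneous")
        net = build_network(cfg)
        pop = apply_variant(net, cfg)
        n = net.n_neurons
        counts = np.bincount(pop.neuron_type, minlength=3)
        assert counts[2] == round(0.2 * n)      # inhibitory
        assert counts[1] == round(0.1 * n)      # bursty excitatory
        assert counts[0] == n - counts[1] - counts[2]
        bursty = pop.neuron_type == 1
        assert np.all(pop.v_c[bursty] == -40.0)
        assert np.all(pop.d[bursty] == 50.0)
        exc = pop.neuron_type != 2
        assert np.all(pop.v_r[exc] >= -62.0)  # Rayleigh offsets are positive

    def test_inhibition_block_zeroes_strength(self):
        cfg = small_config(inhibition_blocked=True)
        net = build_network(cfg)
        pop = apply_variant(net, cfg)
        assert pop.synapse.g_inh == 0.0

    def test_block_is_noop_without_inhibitory_cells(self):
        cfg = small_config(inhibitory_fraction=0.0, inhibition_blocked=True, duration_s=2.0)
        net = build_network(cfg)
        assert net.ei_label.sum() == 0
        r1 = simulate(net, cfg)
        r2 = simulate(net, replace(cfg, inhibition_blocked=False))
        assert r1.n_spikes == r2.n_spikes


class TestDynamics:
    def test_seed_determinism(self):
        cfg = small_config(duration_s=3.0)
        net = build_network(cfg)
        a = simulate(net, cfg)
        b = simulate(net, cfg)
        assert a.n_spikes == b.n_spikes
        for ta, tb in zip(a.spike_times, b.spike_times):
            np.testing.assert_array_equal(ta, tb)

    def test_silent_network_limit(self):
        p = NeuronParams(g_s=0.0, lambda_mini=0.0)
        cfg = small_config(duration_s=3.0, neuron=p)
        net = build_network(cfg)
        assert simulate(net, cfg).n_spikes == 0

    def test_quiet_single_neuron_rests(self):
        p = NeuronParams(g_s=0.0, lambda_mini=0.0)
        spikes = simulate_single_neuron(10.0, params=p)
        assert spikes.size == 0

    def test_mini_driven_rate_order_point_one_hz(self):
        spikes = simulate_single_neuron(200.0, seed=5)
        rate = spikes.size / 200.0
        assert 0.1 / 3 <= rate <= 0.1 * 3

    def test_depression_stays_in_unit_interval(self):
        cfg = small_config(duration_s=2.0, synapse=SynapseParams(g_exc=100.0))
        net = build_network(cfg)
        raster, state = simulate(net, cfg, return_state=True)
        assert raster.n_spikes > 0  # spikes occurred, so D was depressed
        dep = state["depression"]
        assert np.all(dep > 0) and np.all(dep <= 1.0)

    def test_depression_recovers_during_silence(self):
        # spikes early on deplete D; a silent network then relaxes D toward 1
        p = NeuronParams(g_s=0.0, lambda_mini=0.0)
        cfg = small_config(duration_s=1.0, neuron=p)
        net = build_network(cfg)
        _, state = simulate(net, cfg, return_state=True)
        np.testing.assert_allclose(state["depression"], 1.0, atol=1e-6)


class TestBranchingProcess:
    def test_no_offspring(self):
        aset, capped = branching_process(1000, m=0.0, rng_seed=1)
        assert np.all(aset.sizes == 1)
        assert np.all(aset.durations == 1)
        assert not capped.any()

    def test_subcritical_mean_size(self):
        aset, _ = branching_process(200_000, m=0.5, rng_seed=2)
        assert aset.sizes.mean() == pytest.approx(2.0, rel=0.03)

    def test_sizes_are_borel_distributed(self):
        """S of a Poisson(1) Galton-Watson tree follows the Borel law
        P(S = s) = e^{-s} s^{s-1} / s!  (independent closed-form oracle)."""
        from scipy.special import gammaln

        aset, _ = branching_process(300_000, m=1.0, max_generations=10_000, rng_seed=3)
        s = np.arange(1, 8)
        expected = np.exp(-s + (s - 1) * np.log(s) - gammaln(s + 1))
        freq = np.bincount(aset.sizes, minlength=9)[1:8] / aset.sizes.size
        np.testing.assert_allclose(freq, expected, rtol=0.02)

    def test_determinism(self):
        a, _ = branching_process(10_000, m=1.0, rng_seed=9)
        b, _ = branching_process(10_000, m=1.0, rng_seed=9)
        np.testing.assert_array_equal(a.sizes, b.sizes)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            branching_process(0, m=1.0)
        with pytest.raises(ValueError):
            branching_process(10, m=-0.5)
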