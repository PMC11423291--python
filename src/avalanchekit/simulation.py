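"""Forward-Euler network simulation and the branching-process oracle.

Membrane dynamics per neuron (quadratic integrate-and-fire with
adaptation), in mV and ms:

    C dv/dt = k (v - v_r)(v - v_t) - u + I + I0 + eta
    tau_a du/dt = b (v - v_r) - u
    if v >= v_p:  v <- v_c,  u <- u + d

``I`` is the sum of exponentially decaying excitatory and inhibitory
synaptic currents; every presynaptic spike of neuron i adds
``g * D_i`` to each out-neighbour's current, where ``D_i`` is the
presynaptic short-term-depression variable recovering as
``dD/dt = (1 - D)/tau_D`` and dropping multiplicatively ``D <- beta D`` at
each of i's spikes.  ``I0`` is a per-neuron exponentially decaying "mini"
current fed by a Poisson process (rate lambda, amplitude g_m); all minis of
a neuron share one decaying accumulator.  (Internally the n independent
per-neuron Poisson processes are drawn as one population process of rate
``n * lambda`` with uniform neuron assignment — the same law, much faster.)  ``eta`` is white noise with
autocorrelation ``2 g_s delta(t - t')``, discretised Euler-Maruyama style:
each step adds ``sqrt(2 g_s dt) xi / C`` to ``v`` with ``xi ~ N(0, 1)``.

Integration is first-order Euler at dt = 0.1 ms in double precision, with a
divergence guard at |v| = 1000 mV.  Synaptic delivery is instantaneous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .avalanches import AvalancheSet
from .network import Network, PopulationParams, SimulationConfig, apply_variant
from .raster import SpikeRaster

__all__ = ["simulate", "simulate_single_neuron", "branching_process"]


class IntegrationError(RuntimeError):
    pass


@njit(cache=True, fastmath=True)
def _run_kernel(
    n_steps,
    dt,
    # per-neuron state
    v, u, ie, ii, im, dep,
    # per-neuron params
    v_r, v_c, d_inc, is_inh,
    g_spike, beta_spike, dep_step,  # per-neuron: synaptic strength, STD drop, dt/tau_D
    # scalars
    C, k, v_t, v_p, b, tau_a,
    noise_step,  # sqrt(2*g_s*dt)/C, premultiplied
    lam, g_m, decay_m,
    decay_e, decay_i,
    # adjacency
    indptr, targets,
    # outputs
    spike_neuron, spike_step,
):
    n = v.size
    max_spikes = spike_neuron.size
    n_sp = 0
    lam_tot = lam * dt * n  # population mini rate per step
    dt_over_C = dt / C
    dt_over_tau_a = dt / tau_a
    # error reporting uses a flag + break: early returns inside the loop
    # nest (like scalar RNG calls interleaved with the bulk fills) defeat
    # LLVM's vectorisation of the membrane loop and cost ~4x
    err = 0
    err_i = -1
    err_t = 0.0
    chunk = 64  # steps of randomness drawn per bulk fill
    step = 0
    while step < n_steps and err == 0:
        xi = np.random.standard_normal(n * chunk)
        # miniature synaptic events: the union of n independent Poisson
        # processes of rate lam is a population process of rate n*lam
        # with uniformly random neuron assignment (exact equivalence)
        mini_counts = np.random.poisson(lam_tot, chunk)
        mini_idx = np.random.randint(0, n, int(mini_counts.sum()))
        mini_pos = 0
        for c in range(chunk):
            if step >= n_steps or err != 0:
                break
            t = step * dt
            off = c * n
            for _ in range(mini_counts[c]):
                im[mini_idx[mini_pos]] += g_m
                mini_pos += 1
            # branch-free membrane/current update (SIMD-friendly)
            for i in range(n):
                ie[i] *= decay_e
                ii[i] *= decay_i
                im[i] *= decay_m
                dep[i] += dep_step[i] * (1.0 - dep[i])
                vi = v[i]
                itot = ie[i] + ii[i] + im[i]
                dv = (k * (vi - v_r[i]) * (vi - v_t) - u[i] + itot) * dt_over_C
                vi = vi + dv + noise_step * xi[off + i]
                u[i] = u[i] + dt_over_tau_a * (b * (vi - v_r[i]) - u[i])
                v[i] = vi
            # rare-branch scan: spikes, resets, divergence guard; synaptic
            # delivery takes effect from the next step onward
            for i in range(n):
                vi = v[i]
                if vi >= v_p:
                    if n_sp >= max_spikes:
                        err = -2
                        err_i = i
                        err_t = t
                        break
                    spike_neuron[n_sp] = i
                    spike_step[n_sp] = step
                    n_sp += 1
                    amp = g_spike[i] * dep[i]
                    if is_inh[i]:
                        for jj in range(indptr[i], indptr[i + 1]):
                            ii[targets[jj]] += amp
                    else:
                        for jj in range(indptr[i], indptr[i + 1]):
                            ie[targets[jj]] += amp
                    dep[i] *= beta_spike[i]
                    v[i] = v_c[i]
                    u[i] = u[i] + d_inc[i]
                elif vi > 1000.0 or vi < -1000.0:
                    err = -1
                    err_i = i
                    err_t = t
                    break
            step += 1
    return n_sp, err, err_i, err_t


def simulate(
    network: Network,
    config: SimulationConfig,
    population: PopulationParams | None = None,
    record_ids: np.ndarray | None = None,
    return_state: bool = False,
) -> SpikeRaster:
    """Integrate the culture model and return the resulting spike raster.

    ``population`` defaults to :func:`avalanchekit.network.apply_variant`
    applied to the config's variant; ``record_ids`` optionally restricts the
    returned raster to a subset of neurons (all by default).  Identical
    seeds give identical rasters.  With ``return_state`` the final state
    arrays (membrane potential, adaptation, depression) are returned
    alongside the raster.
    """
    if population is None:
        population = apply_variant(network, config)
    n = network.n_neurons
    p = config.neuron
    s = population.synapse
    dt = config.dt_ms
    n_steps = int(round(config.duration_s * 1000.0 / dt))

    rng = np.random.default_rng(config.seed + 2)
    v = population.v_r + rng.uniform(-2.0, 2.0, n)  # start near rest
    u = np.zeros(n)
    ie = np.zeros(n)
    ii = np.zeros(n)
    im = np.zeros(n)
    dep = np.ones(n)
    is_inh = (population.neuron_type == 2).astype(np.int8)
    inh_mask = is_inh.astype(bool)
    g_spike = np.where(inh_mask, s.g_inh, s.g_exc)
    beta_spike = np.where(inh_mask, s.beta_inh, s.beta_exc)
    dep_step = np.where(inh_mask, dt / s.tau_D_inh, dt / s.tau_D_exc)

    spike_neuron = np.empty(config.max_spikes, dtype=np.int32)
    spike_step = np.empty(config.max_spikes, dtype=np.int64)

    # numba uses its own legacy RNG; seed it deterministically from config
    _seed_numba(np.uint32(config.seed % (2**32 - 1) + 1))
    n_sp, err, err_neuron, err_t = _run_kernel(
        n_steps, dt,
        v, u, ie, ii, im, dep,
        population.v_r, population.v_c, population.d, is_inh,
        g_spike, beta_spike, dep_step,
        p.C, p.k, p.v_t, p.v_p, p.b, p.tau_a,
        np.sqrt(2.0 * p.g_s * dt) / p.C,
        p.lambda_mini, p.g_m, np.exp(-dt / p.tau_m),
        np.exp(-dt / s.tau_exc), np.exp(-dt / s.tau_inh),
        network.indptr, network.targets,
        spike_neuron, spike_step,
    )
    if err == -1:
        raise IntegrationError(
            f"membrane potential diverged for neuron {err_neuron} at t = {err_t:.1f} ms"
        )
    if err == -2:
        raise IntegrationError(
            f"spike buffer exhausted ({config.max_spikes}) at t = {err_t:.1f} ms; "
            "raise max_spikes"
        )
    nid = spike_neuron[:n_sp]
    ts = spike_step[:n_sp] * (dt / 1000.0)  # seconds

    if record_ids is None:
        record_ids = np.arange(n)
    spike_times = []
    order = np.argsort(nid, kind="stable")
    nid_sorted = nid[order]
    ts_sorted = ts[order]
    bounds = np.searchsorted(nid_sorted, np.arange(n + 1))
    for i in record_ids:
        spike_times.append(np.sort(ts_sorted[bounds[i]:bounds[i + 1]]))
    raster = SpikeRaster(
        spike_times=spike_times,
        duration=config.duration_s,
        frame_interval=dt / 1000.0,
        positions=network.positions[record_ids],
        ei_label=network.ei_label[record_ids],
        neuron_ids=np.asarray(record_ids),
    )
    if return_state:
        return raster, {"v": v, "u": u, "depression": dep}
    return raster


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def simulate_single_neuron(
    duration_s: float,
    params=None,
    dt_ms: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Spike times (s) of one isolated model neuron driven by minis and noise.

    Convenience wrapper used to check the spontaneous firing rate: with the
    default parameters the mini bombardment produces spikes at of the order
    of 0.1 Hz.
    """
    from .network import NeuronParams

    p = params if params is not None else NeuronParams()
    cfg = SimulationConfig(
        side_length_mm=1.0, density_per_mm2=1.0, duration_s=duration_s,
        dt_ms=dt_ms, seed=seed, neuron=p, max_spikes=1_000_000,
    )
    net = Network(
        positions=np.zeros((1, 2)),
        ei_label=np.zeros(1, dtype=np.int8),
        indptr=np.zeros(2, dtype=np.int64),
        targets=np.empty(0, dtype=np.int64),
        dendrite_radii=np.ones(1),
        axon_lengths=np.ones(1),
    )
    pop = PopulationParams(
        v_r=np.array([p.v_r]), v_c=np.array([p.v_c]), d=np.array([p.d]),
        neuron_type=np.zeros(1, dtype=np.int8), synapse=cfg.synapse,
    )
    raster = simulate(net, cfg, population=pop)
    return raster.spike_times[0]


@njit(cache=True)
def _gw_kernel(n_avalanches, m, max_generations, sizes, durations, capped):
    for a in range(n_avalanches):
        z = 1
        s = 1
        g = 1
        while z > 0 and g < max_generations:
            # offspring of a whole generation: sum of iid Poisson(m) is Poisson(m*z)
            z = np.random.poisson(m * z)
            if z > 0:
                s += z
                g += 1
        sizes[a] = s
        durations[a] = g
        capped[a] = z > 0  # still active when the generation cap hit


def branching_process(
    n_avalanches: int,
    m: float = 1.0,
    max_generations: int = 10_000,
    rng_seed: int = 0,
) -> tuple[AvalancheSet, np.ndarray]:
    """Galton-Watson avalanches with Poisson(m) offspring.

    Each avalanche starts from one active unit; size S is the total number
    of activations and duration T the number of generations.  Simulation is
    generation-wise (one Poisson draw per generation, using that a sum of
    Poissons is Poisson), which is exact for (S, T) and makes a million
    critical avalanches tractable.  Avalanches still active at
    ``max_generations`` are truncated and flagged.

    Returns the avalanche set (bin width 1, arbitrary units) and the
    boolean cap flags.  At ``m = 1`` the ensemble has the mean-field
    critical statistics P(S) ~ S^-1.5, P(T) ~ T^-2, <T>(S) ~ S^0.5.
    """
    if m < 0 or n_avalanches < 1:
        raise ValueError("need m >= 0 and n_avalanches >= 1")
    sizes = np.empty(n_avalanches, dtype=np.int64)
    durations = np.empty(n_avalanches, dtype=np.int64)
    capped = np.empty(n_avalanches, dtype=np.bool_)
    _seed_numba(np.uint32(rng_seed % (2**32 - 1) + 1))
    _gw_kernel(n_avalanches, m, max_generations, sizes, durations, capped)
    aset = AvalancheSet(
        sizes=sizes,
        durations=durations,
        start_bins=np.zeros(n_avalanches, dtype=np.int64),
        bin_width=1.0,
        state="all",
    )
    return aset, capped
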