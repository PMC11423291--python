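"""Spatially embedded synaptic network of a dissociated culture.

Neurons are scattered uniformly over a square region at a target density.
Each neuron grows an axon as a biased random walk: a total length drawn
from a Rayleigh distribution, laid down in 10 um segments whose headings
are Gaussian perturbations (15 degrees s.d.) of the previous heading, the
first heading uniform.  Each neuron also has an effective circular
dendritic tree with Gaussian-distributed radius (150 +- 40 um).  A directed
synapse pre -> post is created with fixed probability whenever the
presynaptic axon polyline crosses the postsynaptic dendritic disk.  Twenty
percent of the neurons, chosen at random, are inhibitory.

The axon-length Rayleigh scale defaults to 950 um (mean axon length
~1.2 mm), matching the millimetre-scale axons of dissociated cultures.
With the 150 um dendritic disks this yields a mean degree of ~30 at
800 neurons/mm^2; tens-of-micron axons (the scale is configurable) give a
degree of ~8 and a network that never leaves the asynchronous low-rate
regime, with no up states at any synaptic strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "SimulationConfig",
    "Network",
    "build_network",
    "apply_variant",
    "PopulationParams",
]


@dataclass
class NeuronParams:
    """Single-cell quadratic integrate-and-fire parameters.

    Voltages in mV, times in ms; ``C`` is the normalised membrane constant
    of the quadratic model (the equations are treated as dimensionally
    consistent in mV and ms).
    """

    C: float = 100.0        # ms, normalised membrane constant
    k: float = 0.7          # 1/mV
    v_r: float = -60.0      # mV, resting potential
    v_t: float = -40.0      # mV, threshold potential
    v_p: float = 30.0       # mV, spike peak / firing cutoff
    v_c: float = -50.0      # mV, reset potential (-40 for bursty cells)
    b: float = -2.0
    d: float = 100.0        # mV, adaptation increment per spike (50 for bursty)
    tau_a: float = 33.0     # ms, adaptation time constant
    g_s: float = 30.0       # mV, white-noise amplitude (autocorr 2*g_s*delta)
    lambda_mini: float = 0.1  # 1/ms, Poisson rate of miniature events
    g_m: float = 30.0       # mV, mini amplitude
    tau_m: float = 10.0     # ms, mini current decay

    def __post_init__(self) -> None:
        if not self.v_r < self.v_t:
            raise ValueError("need v_r < v_t")
        if self.tau_a <= 0 or self.tau_m <= 0:
            raise ValueError("time constants must be positive")
        if self.lambda_mini < 0:
            raise ValueError("lambda_mini must be non-negative")


@dataclass
class SynapseParams:
    """Synaptic strengths, current decays, and short-term depression."""

    g_exc: float = 40.0      # mV; control parameter for up-state spacing
    g_inh: float = -50.0     # mV
    tau_exc: float = 10.0    # ms
    tau_inh: float = 20.0    # ms
    tau_D_exc: float = 2000.0   # ms, depression recovery (excitatory)
    tau_D_inh: float = 200.0    # ms, depression recovery (inhibitory)
    beta_exc: float = 0.8    # multiplicative D drop per spike
    beta_inh: float = 0.95

    def __post_init__(self) -> None:
        for tau in (self.tau_exc, self.tau_inh, self.tau_D_exc, self.tau_D_inh):
            if tau <= 0:
                raise ValueError("synaptic time constants must be positive")
        for beta in (self.beta_exc, self.beta_inh):
            if not 0 < beta < 1:
                raise ValueError("depression factors must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Geometry, integration, and variant switches for one simulation."""

    side_length_mm: float = 2.5
    density_per_mm2: float = 800.0
    duration_s: float = 300.0
    dt_ms: float = 0.1
    seed: int = 0
    variant: str = "homogeneous"  # or "heterogeneous"
    inhibition_blocked: bool = False
    inhibitory_fraction: float = 0.2
    bursty_fraction: float = 0.1        # heterogeneous variant only
    connection_probability: float = 0.13
    axon_scale_um: float = 950.0        # Rayleigh scale; see module docstring
    axon_segment_um: float = 10.0
    axon_heading_std_deg: float = 15.0
    dendrite_mean_um: float = 150.0
    dendrite_std_um: float = 40.0
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    max_spikes: int = 30_000_000
    keep_axon_geometry: bool = False

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.duration_s <= 0:
            raise ValueError("dt and duration must be positive")
        if self.side_length_mm <= 0 or self.density_per_mm2 <= 0:
            raise ValueError("geometry must be positive")
        if self.variant not in {"homogeneous", "heterogeneous"}:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_neurons(self) -> int:
        return int(round(self.density_per_mm2 * self.side_length_mm**2))


def scaled_down_config(
    seed: int = 0,
    duration_s: float = 300.0,
    variant: str = "homogeneous",
    inhibition_blocked: bool = False,
) -> SimulationConfig:
    """Desk-scale culture configuration: 2.5 x 2.5 mm, ~5,000 neurons.

    The excitatory synaptic strength is the control parameter for the
    spacing of up states; at this reduced scale it is re-tuned (single
    scalar sweep) to 60 mV to restore the quasi-periodic up/down
    alternation that the full-scale culture shows near 40 mV.
    """
    return SimulationConfig(
        side_length_mm=2.5,
        density_per_mm2=800.0,
        duration_s=duration_s,
        seed=seed,
        variant=variant,
        inhibition_blocked=inhibition_blocked,
        synapse=SynapseParams(g_exc=60.0),
    )


@dataclass
class Network:
    """Directed synaptic graph with spatial embedding and E/I labels."""

    positions: np.ndarray       # (n, 2) um
    ei_label: np.ndarray        # int8; 0 = excitatory, 1 = inhibitory
    indptr: np.ndarray          # CSR out-adjacency
    targets: np.ndarray
    dendrite_radii: np.ndarray  # um
    axon_lengths: np.ndarray    # um
    axon_polylines: list[np.ndarray] | None = None

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_connections(self) -> int:
        return int(self.targets.size)

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def write_edge_list(self, path, weights: np.ndarray | None = None) -> None:
        """Delimited (pre, post, weight) export; weight defaults to +-1 by E/I."""
        lines = []
        for pre in range(self.n_neurons):
            w = -1.0 if self.ei_label[pre] else 1.0
            for jj in range(self.indptr[pre], self.indptr[pre + 1]):
                wt = weights[jj] if weights is not None else w
                lines.append(f"{pre}\t{int(self.targets[jj])}\t{wt}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _grow_axon(
    x0: float, y0: float, length: float, segment: float, heading_std: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Axon polyline vertices, biased random walk in fixed-length segments."""
    n_seg = max(int(np.ceil(length / segment)), 1)
    headings = np.empty(n_seg)
    headings[0] = rng.uniform(0.0, 2.0 * np.pi)
    if n_seg > 1:
        headings[1:] = rng.normal(0.0, heading_std, n_seg - 1)
        headings = np.cumsum(headings)
    seg_lengths = np.full(n_seg, segment)
    seg_lengths[-1] = length - segment * (n_seg - 1)
    pts = np.empty((n_seg + 1, 2))
    pts[0] = (x0, y0)
    pts[1:, 0] = x0 + np.cumsum(seg_lengths * np.cos(headings))
    pts[1:, 1] = y0 + np.cumsum(seg_lengths * np.sin(headings))
    return pts


def _polyline_hits_disk(pts: np.ndarray, center: np.ndarray, radius: float) -> bool:
    """True if any segment of the polyline comes within ``radius`` of ``center``."""
    return bool(
        _polyline_hits_disks(pts, center[None, :], np.array([radius]))[0]
    )


def _polyline_hits_disks(
    pts: np.ndarray, centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Vectorised segment-vs-disk test: for each disk, does any segment hit it?"""
    a = pts[:-1]                      # (m, 2)
    ab = pts[1:] - a                  # (m, 2)
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12)  # (m,)
    ac = centers[:, None, :] - a[None, :, :]                  # (c, m, 2)
    t = np.clip(np.einsum("cmj,mj->cm", ac, ab) / denom, 0.0, 1.0)
    diff = ac - t[:, :, None] * ab[None, :, :]
    d2 = np.einsum("cmj,cmj->cm", diff, diff)
    return np.any(d2 <= (radii**2)[:, None], axis=1)


def _axon_crossings(
    pts: np.ndarray, centers: np.ndarray, radii: np.ndarray, block: int = 8
) -> np.ndarray:
    """Which dendritic disks does this axon polyline cross?

    Two-level test: the polyline is covered by bounding circles over blocks
    of ``block`` segments; only disks touching a bounding circle get the
    exact segment-versus-disk distance test for that block.
    """
    m = pts.shape[0] - 1
    hit = np.zeros(centers.shape[0], dtype=bool)
    for j0 in range(0, m, block):
        sub = pts[j0 : min(j0 + block, m) + 1]
        c = sub.mean(axis=0)
        r_cover = np.sqrt(((sub - c) ** 2).sum(axis=1).max())
        rest = np.flatnonzero(~hit)
        if rest.size == 0:
            break
        d = np.hypot(centers[rest, 0] - c[0], centers[rest, 1] - c[1])
        maybe = rest[d <= r_cover + radii[rest]]
        if maybe.size:
            hit[maybe] = _polyline_hits_disks(sub, centers[maybe], radii[maybe])
    return hit


def build_network(config: SimulationConfig, rng_seed: int | None = None) -> Network:
    """Build the spatial culture network; deterministic given the seed.

    Connection rule: pre -> post whenever pre's axon polyline intersects
    post's dendritic disk, accepted with ``connection_probability``; at most
    one connection per ordered pair and no self-connections.
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    n = config.n_neurons
    L = config.side_length_mm * 1000.0  # um
    positions = rng.uniform(0.0, L, size=(n, 2))
    radii = np.clip(
        rng.normal(config.dendrite_mean_um, config.dendrite_std_um, n), 1.0, None
    )
    axon_lengths = rng.rayleigh(config.axon_scale_um, n)
    heading_std = np.deg2rad(config.axon_heading_std_deg)

    ei = np.zeros(n, dtype=np.int8)
    n_inh = int(round(config.inhibitory_fraction * n))
    ei[rng.choice(n, size=n_inh, replace=False)] = 1

    # coarse spatial grid for candidate postsynaptic neurons
    reach = axon_lengths.max() + radii.max() + 1.0
    cell = max(reach / 2.0, 1.0)
    nx = max(int(np.ceil(L / cell)), 1)
    gx = np.minimum((positions[:, 0] / cell).astype(np.int64), nx - 1)
    gy = np.minimum((positions[:, 1] / cell).astype(np.int64), nx - 1)
    order = np.argsort(gx * nx + gy, kind="stable")
    cell_ids = (gx * nx + gy)[order]
    cell_starts = np.searchsorted(cell_ids, np.arange(nx * nx))
    cell_ends = np.searchsorted(cell_ids, np.arange(nx * nx), side="right")

    indptr = np.zeros(n + 1, dtype=np.int64)
    target_chunks: list[np.ndarray] = []
    polylines: list[np.ndarray] | None = [] if config.keep_axon_geometry else None
    for pre in range(n):
        pts = _grow_axon(
            positions[pre, 0], positions[pre, 1], axon_lengths[pre],
            config.axon_segment_um, heading_std, rng,
        )
        if polylines is not None:
            polylines.append(pts)
        cx, cy = gx[pre], gy[pre]
        span = int(np.ceil((axon_lengths[pre] + radii.max()) / cell)) + 1
        cand: list[np.ndarray] = []
        for ix in range(max(cx - span, 0), min(cx + span + 1, nx)):
            for iy in range(max(cy - span, 0), min(cy + span + 1, nx)):
                cid = ix * nx + iy
                cand.append(order[cell_starts[cid]:cell_ends[cid]])
        candidates = np.concatenate(cand) if cand else np.empty(0, dtype=np.int64)
        candidates = candidates[candidates != pre]
        if candidates.size:
            # cheap prefilter: soma of post within axon reach + dendrite radius
            d_soma = np.hypot(
                positions[candidates, 0] - positions[pre, 0],
                positions[candidates, 1] - positions[pre, 1],
            )
            near = d_soma <= axon_lengths[pre] + radii[candidates]
            candidates = candidates[near]
        if candidates.size:
            hit = _axon_crossings(pts, positions[candidates], radii[candidates])
            crossed = candidates[hit]
            accepted = crossed[rng.random(crossed.size) < config.connection_probability]
        else:
            accepted = np.empty(0, dtype=np.int64)
        tgt = np.sort(accepted).astype(np.int64)
        target_chunks.append(tgt)
        indptr[pre + 1] = indptr[pre] + tgt.size
    targets = (
        np.concatenate(target_chunks) if target_chunks else np.empty(0, dtype=np.int64)
    )
    return Network(
        positions=positions,
        ei_label=ei,
        indptr=indptr,
        targets=targets,
        dendrite_radii=radii,
        axon_lengths=axon_lengths,
        axon_polylines=polylines,
    )


@dataclass
class PopulationParams:
    """Per-neuron parameter arrays resolved from the variant rules."""

    v_r: np.ndarray
    v_c: np.ndarray
    d: np.ndarray
    neuron_type: np.ndarray  # 0 = standard exc, 1 = bursty exc, 2 = inhibitory
    synapse: SynapseParams


def apply_variant(
    network: Network, config: SimulationConfig, rng_seed: int | None = None
) -> PopulationParams:
    """Resolve per-neuron parameters for the configured variant.

    Homogeneous: every neuron uses the base parameters.  Heterogeneous: the
    excitatory population is split into standard and bursty cells (bursty:
    reset at -40 mV, adaptation increment 50 mV), and every excitatory cell
    gets a resting potential of -62 mV plus a Rayleigh(sigma = 2 mV) offset.
    Blocking inhibition (the picrotoxin analogue) zeroes the inhibitory
    synaptic strength without touching the graph.
    """
    seed = (config.seed if rng_seed is None else rng_seed) + 1
    rng = np.random.default_rng(seed)
    n = network.n_neurons
    p = config.neuron
    v_r = np.full(n, p.v_r)
    v_c = np.full(n, p.v_c)
    d = np.full(n, p.d)
    ntype = np.where(network.ei_label == 1, 2, 0).astype(np.int8)

    if config.variant == "heterogeneous":
        exc = np.flatnonzero(ntype == 0)
        n_bursty = int(round(config.bursty_fraction * n))
        if n_bursty > exc.size:
            raise ValueError("bursty fraction exceeds the excitatory population")
        bursty = rng.choice(exc, size=n_bursty, replace=False)
        ntype[bursty] = 1
        v_c[bursty] = -40.0
        d[bursty] = 50.0
        exc_all = np.flatnonzero(ntype != 2)
        v_r[exc_all] = -62.0 + rng.rayleigh(2.0, exc_all.size)

    synapse = replace(
        config.synapse, g_inh=0.0 if config.inhibition_blocked else config.synapse.g_inh
    )
    return PopulationParams(v_r=v_r, v_c=v_c, d=d, neuron_type=ntype, synapse=synapse)
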