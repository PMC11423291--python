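"""End-to-end analysis: raster -> states -> avalanches -> exponents -> report.

The pipeline produces, per recording or simulation, a complete per-state
exponent summary: for each of the up and down states it detects
avalanches across a grid of temporal bin widths (pooled over an ensemble of
random neuron patches), runs the finite-size scaling collapse, decides
between the power-law and exponential-like families with the KS gate,
estimates the size-duration exponent gamma, and checks the crackling-noise
exponent relations.  Results are written as a JSON report (validated by a
pydantic schema), a delimited avalanche table, and optional log-log
distribution figures.

Conventions (see docs/methods.md for rationale):

* The analysed population is restricted to a circular patch whose radius
  is chosen so that the up-state activity is of the order of one event per
  base time bin; for the scaled-down culture simulations that is 0.5 mm.
* State detection uses the recording's base frame, a Gaussian kernel of 5
  frames (experiments, 5 ms frames) or 20 frames (simulations, 0.1 ms
  steps), and the fixed Schmitt thresholds 1e-3 / 3e-4.
* The family gate tests the power law with the exponent fixed from the
  collapse, requires the qualifying range to reach into the tail
  (tail_anchor 0.25) and to span at least one decade at some bin width,
  and evaluates p-values at the per-patch-iteration sample count.
* gamma is fitted on the avalanches at the base bin width of each state's
  grid.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import plstats, scaling
from .avalanches import AvalancheSet, avalanches_in_intervals, isi_stats, mean_duration_vs_size
from .network import SimulationConfig, build_network
from .raster import SpikeRaster, bin_raster, read_spike_raster
from .report import RecordingReport, StateResult
from .simulation import simulate
from .states import (
    LOWER_THRESHOLD,
    SIGMA_FRAMES_EXPERIMENT,
    SIGMA_FRAMES_SIMULATION,
    UPPER_THRESHOLD,
    population_rate,
    schmitt_segment,
    smooth_rate,
    state_duration_stats,
)

logger = logging.getLogger("avalanchekit.pipeline")

__all__ = ["AnalysisConfig", "run_full_analysis", "analyze_raster"]

UP_BIN_FACTORS = (1, 2, 4, 8)
DOWN_BIN_FACTORS_SIM = (64, 128, 256, 512, 1024, 2048)  # 6.4 - 205 ms at dt = 0.1 ms
DOWN_BIN_FACTORS_EXP = (2, 4, 8, 16, 32, 64)            # 10 - 320 ms at 5 ms frames


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    raster_path: str | None = None
    simulation: SimulationConfig | None = None
    source: str = "auto"  # "experiment" | "simulation" | "auto"
    upper_threshold: float = UPPER_THRESHOLD
    lower_threshold: float = LOWER_THRESHOLD
    sigma_frames: float | None = None  # default: 5 (experiment) / 20 (simulation)
    patch_radius_um: float | None = None  # circular analysis patch; None = all neurons
    n_patches: int = 100
    patch_fraction: float = 0.5
    up_bin_factors: tuple[int, ...] = UP_BIN_FACTORS
    down_bin_factors: tuple[int, ...] | None = None
    p_gate: float = 0.1
    tail_anchor: float = 0.25
    seed: int = 0
    out_dir: str | None = None
    make_figures: bool = False
    label: str = "recording"

    def __post_init__(self) -> None:
        if (self.raster_path is None) == (self.simulation is None):
            raise ValueError("exactly one of raster_path or simulation must be given")

    def resolve_source(self, raster: SpikeRaster | None = None) -> str:
        """Experiment or simulation conventions (smoothing sigma, bin grids).

        "auto" treats direct simulator runs — and rasters with sub-ms frames,
        which only the simulator produces — as simulations.
        """
        if self.source != "auto":
            return self.source
        if self.simulation is not None:
            return "simulation"
        if raster is not None and raster.frame_interval < 1e-3:
            return "simulation"
        return "experiment"

    @property
    def is_simulation(self) -> bool:
        return self.resolve_source() == "simulation"


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - context is the point
                raise StageError(name, exc) from exc
            logger.info("stage %s: %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("input")
def _load_raster(config: AnalysisConfig) -> SpikeRaster:
    if config.raster_path is not None:
        return read_spike_raster(config.raster_path)
    sim = config.simulation
    net = build_network(sim)
    return simulate(net, sim)


@_stage("patch_restriction")
def _restrict_patch(raster: SpikeRaster, config: AnalysisConfig) -> SpikeRaster:
    if config.patch_radius_um is None:
        return raster
    if raster.positions is None:
        raise ValueError("patch_radius_um requires neuron positions")
    center = raster.positions.mean(axis=0)
    d2 = ((raster.positions - center) ** 2).sum(axis=1)
    idx = np.flatnonzero(d2 <= config.patch_radius_um**2)
    if idx.size == 0:
        raise ValueError("no neurons inside the analysis patch")
    return raster.subset(idx)


@_stage("state_detection")
def _detect_states(raster: SpikeRaster, config: AnalysisConfig):
    sigma = config.sigma_frames
    if sigma is None:
        sigma = (
            SIGMA_FRAMES_SIMULATION
            if config.resolve_source(raster) == "simulation"
            else SIGMA_FRAMES_EXPERIMENT
        )
    binned = bin_raster(raster, raster.frame_interval)
    rate = population_rate(binned)
    seg = schmitt_segment(
        smooth_rate(rate, sigma), config.upper_threshold, config.lower_threshold
    )
    return seg


@_stage("avalanche_detection")
def _patch_avalanches(
    raster: SpikeRaster,
    intervals: list[tuple[float, float]],
    bin_factors: tuple[int, ...],
    config: AnalysisConfig,
    state: str,
) -> dict[int, list[AvalancheSet]]:
    """Per bin factor, the list of per-patch avalanche sets for one state."""
    rng = np.random.default_rng(config.seed + (1 if state == "up" else 2))
    n = raster.n_neurons
    k = max(int(config.patch_fraction * n), 1)
    base = raster.frame_interval
    out: dict[int, list[AvalancheSet]] = {bf: [] for bf in bin_factors}
    for pid in range(config.n_patches):
        sel = rng.choice(n, size=k, replace=False)
        chunks = [raster.spike_times[i] for i in sel if raster.spike_times[i].size]
        pooled = np.sort(np.concatenate(chunks)) if chunks else np.empty(0)
        for bf in bin_factors:
            out[bf].append(
                avalanches_in_intervals(
                    pooled, intervals, bf * base, state=state, patch_id=pid
                )
            )
    return out


def _pool(sets: list[AvalancheSet]) -> AvalancheSet:
    merged = sets[0]
    for s in sets[1:]:
        merged = merged.merged_with(s)
    return merged


def _state_distributions(pooled: dict[int, AvalancheSet], observable: str):
    dists = []
    for bf, aset in pooled.items():
        values = aset.sizes if observable == "size" else aset.durations
        try:
            dists.append(
                scaling.empirical_pdf(
                    values,
                    observable=observable,
                    bin_width=aset.bin_width,
                    bin_factor=bf,
                )
            )
        except scaling.DegenerateDistributionError:
            logger.warning("degenerate %s distribution at bin factor %d", observable, bf)
    return dists


def _gate_state(
    per_patch: dict[int, list[AvalancheSet]],
    pooled: dict[int, AvalancheSet],
    exponent: float,
    observable: str,
    config: AnalysisConfig,
) -> plstats.PowerLawFit | None:
    """Best extended power-law range across bin factors at the collapse exponent.

    Returns the winning fit (with per-patch aggregated p-value) or None when
    no bin width admits an extended qualifying range — the exponential-like
    verdict.
    """
    best: plstats.PowerLawFit | None = None
    best_bf = None
    for bf, aset in pooled.items():
        values = aset.sizes if observable == "size" else aset.durations
        if values.size < 50:
            continue
        fit = plstats.fit_power_law_range(
            values,
            p_gate=config.p_gate,
            iterations=config.n_patches,
            fixed_exponent=exponent,
            tail_anchor=config.tail_anchor,
        )
        if fit.extended and (best is None or fit.decades > best.decades):
            best = fit
            best_bf = bf
    if best is None:
        return None
    # per-iteration p-values at the selected range (mean +- SEM convention)
    ps = []
    for aset in per_patch[best_bf]:
        values = aset.sizes if observable == "size" else aset.durations
        inside = values[(values >= best.x_low) & (values <= best.x_high)]
        if inside.size < 10:
            continue
        d = plstats.ks_statistic(inside, best.exponent, best.x_low, best.x_high)
        ps.append(plstats.ks_pvalue(d, inside.size))
    if ps:
        best.p_value_mean, best.p_value_sem = plstats.aggregate_pvalues(ps)
    best.exponent_ml = _ml_refit(pooled[best_bf], best, observable)
    return best


def _ml_refit(pooled: AvalancheSet, fit: plstats.PowerLawFit, observable: str) -> float:
    """Maximum-likelihood exponent within the selected range (the per-range
    estimator; the collapse exponent used for range selection is global)."""
    x = pooled.sizes if observable == "size" else pooled.durations
    inr = x[(x >= fit.x_low) & (x <= fit.x_high)].astype(float)
    return plstats.fit_exponent_ml(
        float(np.sum(np.log(inr))), inr.size, fit.x_low, fit.x_high
    )


@_stage("scaling_analysis")
def _analyse_state(
    per_patch: dict[int, list[AvalancheSet]],
    config: AnalysisConfig,
    state: str,
    pooled: dict[int, AvalancheSet] | None = None,
) -> StateResult:
    if pooled is None:
        pooled = {bf: _pool(sets) for bf, sets in per_patch.items()}
    n_avalanches = {bf: len(a) for bf, a in pooled.items()}
    total = sum(n_avalanches.values())
    if total == 0 or all(len(a) < 50 for a in pooled.values()):
        return StateResult(state=state, family="undefined", n_avalanches=n_avalanches)

    dist_S = _state_distributions(pooled, "size")
    dist_T = _state_distributions(pooled, "duration")
    if len(dist_S) < 3 or len(dist_T) < 3:
        return StateResult(state=state, family="undefined", n_avalanches=n_avalanches)

    base_bf = min(per_patch)
    gamma = mean_duration_vs_size(pooled[base_bf])

    try:
        col_S = scaling.collapse_power_law(dist_S)
        col_T = scaling.collapse_power_law(dist_T)
    except scaling.CollapseInfeasibleError:
        # distributions too narrow to overlap after rescaling: no exponents
        logger.warning("%s state: collapse infeasible; reporting family undefined", state)
        return StateResult(
            state=state, family="undefined", n_avalanches=n_avalanches,
            gamma=None if not np.isfinite(gamma["gamma"]) else gamma["gamma"],
            gamma_unc=None if not np.isfinite(gamma.get("gamma_se", np.nan)) else gamma["gamma_se"],
        )
    gate_S = _gate_state(per_patch, pooled, col_S.exponent, "size", config)
    gate_T = _gate_state(per_patch, pooled, col_T.exponent, "duration", config)

    if gate_S is not None:
        family = "power_law"
        tau, tau_unc = col_S.exponent, col_S.exponent_unc
        alpha, alpha_unc = col_T.exponent, col_T.exponent_unc
        beta_S, beta_S_unc = col_S.beta, col_S.beta_unc
        beta_T, beta_T_unc = col_T.beta, col_T.beta_unc
    else:
        family = "exponential_like"
        tau = tau_unc = alpha = alpha_unc = None
        try:
            exp_S = scaling.collapse_exponential(dist_S)
            exp_T = scaling.collapse_exponential(dist_T)
            beta_S, beta_S_unc = exp_S.beta, exp_S.beta_unc
            beta_T, beta_T_unc = exp_T.beta, exp_T.beta_unc
        except scaling.CollapseInfeasibleError:
            beta_S = beta_T = None
            beta_S_unc = beta_T_unc = np.nan

    relation = None
    if family == "power_law" and tau is not None and tau > 1 and np.isfinite(gamma["gamma"]):
        relation = scaling.check_scaling_relation(
            tau, alpha, gamma["gamma"], tau_unc or 0.0, alpha_unc or 0.0,
            gamma["gamma_se"],
        )
    beta_relation = None
    if beta_S is not None and beta_T is not None:
        beta_relation = scaling.check_beta_relation(
            beta_T, beta_S, gamma["gamma"] if np.isfinite(gamma["gamma"]) else 0.0,
            beta_T_unc if np.isfinite(beta_T_unc) else 0.0,
            beta_S_unc if np.isfinite(beta_S_unc) else 0.0,
            gamma["gamma_se"] if np.isfinite(gamma.get("gamma_se", np.nan)) else 0.0,
        )

    def _fit_dict(fit: plstats.PowerLawFit | None):
        if fit is None:
            return None
        return {
            "exponent": fit.exponent,
            "exponent_ml": fit.exponent_ml,
            "x_low": fit.x_low,
            "x_high": fit.x_high,
            "d_e": fit.d_e,
            "p_value": fit.p_value,
            "p_value_mean": fit.p_value_mean,
            "p_value_sem": fit.p_value_sem,
            "n": fit.n,
            "decades": fit.decades,
        }

    return StateResult(
        state=state,
        family=family,
        n_avalanches=n_avalanches,
        tau=tau,
        tau_unc=tau_unc,
        alpha=alpha,
        alpha_unc=alpha_unc,
        beta_S=beta_S,
        beta_S_unc=None if not np.isfinite(beta_S_unc) else beta_S_unc,
        beta_T=beta_T,
        beta_T_unc=None if not np.isfinite(beta_T_unc) else beta_T_unc,
        gamma=None if not np.isfinite(gamma["gamma"]) else gamma["gamma"],
        gamma_unc=None if not np.isfinite(gamma.get("gamma_se", np.nan)) else gamma["gamma_se"],
        size_fit=_fit_dict(gate_S),
        duration_fit=_fit_dict(gate_T),
        scaling_relation=relation,
        beta_relation=beta_relation,
    )


def analyze_raster(raster: SpikeRaster, config: AnalysisConfig) -> RecordingReport:
    """Run state segmentation and per-state avalanche analysis on a raster."""
    patch = _restrict_patch(raster, config)
    logger.info("analysis population: %d of %d neurons", patch.n_neurons, raster.n_neurons)
    seg = _detect_states(patch, config)
    durations = state_duration_stats(seg)
    isi = isi_stats(patch, seg)

    if config.down_bin_factors is not None:
        down_bins = tuple(config.down_bin_factors)
    else:
        down_bins = (
            DOWN_BIN_FACTORS_SIM
            if config.resolve_source(patch) == "simulation"
            else DOWN_BIN_FACTORS_EXP
        )

    states = {}
    pooled_sets: dict[str, dict[int, AvalancheSet]] = {}
    for state, bins in (("up", tuple(config.up_bin_factors)), ("down", down_bins)):
        intervals = seg.intervals_of(state)
        per_patch = _patch_avalanches(patch, intervals, bins, config, state)
        pooled_sets[state] = {bf: _pool(sets) for bf, sets in per_patch.items()}
        states[state] = _analyse_state(per_patch, config, state, pooled_sets[state])

    report = RecordingReport(
        label=config.label,
        seed=config.seed,
        n_neurons=patch.n_neurons,
        duration_s=patch.duration,
        frame_interval_s=patch.frame_interval,
        state_durations=durations,
        isi=isi,
        up=states["up"],
        down=states["down"],
    )
    if config.out_dir is not None:
        _write_outputs(report, seg, pooled_sets, config)
    return report


def run_full_analysis(config: AnalysisConfig) -> RecordingReport:
    """Load or simulate the input raster, then run the complete analysis."""
    raster = _load_raster(config)
    return analyze_raster(raster, config)


@_stage("outputs")
def _write_outputs(
    report: RecordingReport,
    seg,
    pooled_sets: dict[str, dict[int, AvalancheSet]],
    config: AnalysisConfig,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{config.label}_report.json").write_text(
        report.model_dump_json(indent=2), encoding="utf-8"
    )
    seg.write_bed(out / f"{config.label}_states.bed")
    with open(out / f"{config.label}_avalanches.tsv", "w", encoding="utf-8") as fh:
        fh.write("bin_width_s\tstate\tstart_bin\tT_bins\tS_spikes\n")
        for state, by_bin in pooled_sets.items():
            aset = by_bin[min(by_bin)]  # base bin width of the state's grid
            for b, t, s in zip(aset.start_bins, aset.durations, aset.sizes):
                fh.write(f"{aset.bin_width!r}\t{state}\t{b}\t{t}\t{s}\n")
    if config.make_figures:
        _write_figures(pooled_sets, config, out)


def _write_figures(
    pooled_sets: dict[str, dict[int, AvalancheSet]],
    config: AnalysisConfig,
    out: Path,
) -> None:
    """Log-log avalanche size/duration distributions per state and bin width."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for row, observable in enumerate(("size", "duration")):
        for col, (state, by_bin) in enumerate(pooled_sets.items()):
            ax = axes[row, col]
            for bf, aset in by_bin.items():
                values = aset.sizes if observable == "size" else aset.durations
                try:
                    d = scaling.empirical_pdf(
                        values, observable=observable, bin_factor=bf
                    )
                except scaling.DegenerateDistributionError:
                    continue
                ax.loglog(d.bin_centers, d.density, "o-", ms=3, lw=0.8,
                          label=f"bin x{bf}")
            ax.set_title(f"{state} state")
            ax.set_xlabel("S (spikes)" if observable == "size" else "T (bins)")
            ax.set_ylabel("P(S)" if observable == "size" else "P(T)")
            if ax.has_data():
                ax.legend(fontsize=7)
    fig.suptitle(config.label)
    fig.tight_layout()
    fig.savefig(out / f"{config.label}_distributions.png", dpi=120)
    plt.close(fig)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        from .network import NeuronParams, SynapseParams

        neuron = NeuronParams(**sim.pop("neuron", {}))
        synapse = SynapseParams(**sim.pop("synapse", {}))
        sim = SimulationConfig(neuron=neuron, synapse=synapse, **sim)
    for key in ("up_bin_factors", "down_bin_factors"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(simulation=sim, **raw)
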