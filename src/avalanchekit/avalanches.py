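"""Neuronal-avalanche detection, patch subsampling, and ISI statistics.

An avalanche is the maximal sequence of consecutive time bins that each
contain at least one spike (from any neuron), bounded by empty bins.  Its
duration ``T`` is the number of bins in the run and its size ``S`` the total
number of spikes, so ``S >= T >= 1`` always.  Because the analysis is run
separately inside up and down states, detection is censored at state
boundaries: the bin grid restarts at the start of each state interval and a
run never bridges two intervals.

To emulate the limited experimental field of view (and to build an ensemble
over which goodness-of-fit p-values can be averaged), avalanches are pooled
over many random "patches": subsets of 50% of the neurons drawn uniformly
without replacement, optionally first restricted to a circular region of
the culture (radius 0.5 mm for excitatory-only simulations, 0.8 mm when
inhibition is present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import BinnedRaster, SpikeRaster
from .states import StateSegmentation

__all__ = [
    "Avalanche",
    "AvalancheSet",
    "PatchSpec",
    "restrict_to_state",
    "detect_avalanches",
    "avalanches_in_intervals",
    "sample_patches",
    "mean_duration_vs_size",
    "isi_stats",
]


@dataclass(frozen=True)
class Avalanche:
    start_bin: int
    T: int  # duration in bins
    S: int  # size in spikes

    def __post_init__(self) -> None:
        if self.T < 1 or self.S < self.T:
            raise ValueError(f"invalid avalanche T={self.T}, S={self.S} (need S >= T >= 1)")


@dataclass
class AvalancheSet:
    """Ensemble of avalanches detected at one bin width in one state.

    Stored as parallel arrays (sizes, durations, start bins) for
    efficiency; :attr:`avalanches` materialises :class:`Avalanche` records
    on demand.
    """

    sizes: np.ndarray
    durations: np.ndarray
    start_bins: np.ndarray
    bin_width: float
    state: str = "all"
    patch_id: int | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        self.start_bins = np.asarray(self.start_bins, dtype=np.int64)
        if self.sizes.size:
            if self.durations.min() < 1 or np.any(self.sizes < self.durations):
                raise ValueError("every avalanche needs S >= T >= 1")

    @classmethod
    def from_avalanches(
        cls,
        avalanches: list[Avalanche],
        bin_width: float,
        state: str = "all",
        patch_id: int | None = None,
    ) -> "AvalancheSet":
        return cls(
            sizes=np.array([a.S for a in avalanches], dtype=np.int64),
            durations=np.array([a.T for a in avalanches], dtype=np.int64),
            start_bins=np.array([a.start_bin for a in avalanches], dtype=np.int64),
            bin_width=bin_width,
            state=state,
            patch_id=patch_id,
        )

    @property
    def avalanches(self) -> list[Avalanche]:
        return [
            Avalanche(start_bin=int(b), T=int(t), S=int(s))
            for b, t, s in zip(self.start_bins, self.durations, self.sizes)
        ]

    @property
    def total_spikes(self) -> int:
        return int(self.sizes.sum()) if self.sizes.size else 0

    def __len__(self) -> int:
        return int(self.sizes.size)

    def merged_with(self, other: "AvalancheSet") -> "AvalancheSet":
        if not np.isclose(self.bin_width, other.bin_width):
            raise ValueError("cannot pool avalanche sets at different bin widths")
        return AvalancheSet(
            sizes=np.concatenate((self.sizes, other.sizes)),
            durations=np.concatenate((self.durations, other.durations)),
            start_bins=np.concatenate((self.start_bins, other.start_bins)),
            bin_width=self.bin_width,
            state=self.state,
        )


@dataclass
class PatchSpec:
    """Specification of the patch-subsampling ensemble.

    ``random_fraction`` draws ``floor(fraction * N)`` neurons uniformly
    without replacement per patch; ``circular`` first restricts to the disk
    of ``radius_um`` around ``center_um`` (requires positions) and then
    applies the fraction.
    """

    mode: str = "random_fraction"  # or "circular"
    fraction: float = 0.5
    n_patches: int = 100
    radius_um: float | None = None
    center_um: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.mode not in {"random_fraction", "circular"}:
            raise ValueError(f"unknown patch mode {self.mode!r}")
        if self.mode == "circular" and self.radius_um is None:
            raise ValueError("circular mode requires radius_um")


def restrict_to_state(
    raster: SpikeRaster, seg: StateSegmentation, state: str
) -> tuple[SpikeRaster, list[tuple[float, float]]]:
    """Keep only spikes inside intervals of the requested state label.

    Returns the restricted raster together with the list of state intervals,
    which downstream avalanche detection uses so that no avalanche ever
    bridges two separate intervals of the same state.
    """
    intervals = seg.intervals_of(state)
    if not intervals:
        warnings.warn(f"segmentation contains no {state!r} intervals; empty raster")
    edges = np.array([b for iv in intervals for b in iv]) if intervals else np.empty(0)
    new_times = []
    for t in raster.spike_times:
        if t.size == 0 or edges.size == 0:
            new_times.append(np.empty(0))
            continue
        # even searchsorted index => inside an interval [start, end)
        idx = np.searchsorted(edges, t, side="right")
        new_times.append(t[idx % 2 == 1])
    restricted = SpikeRaster(
        spike_times=new_times,
        duration=raster.duration,
        frame_interval=raster.frame_interval,
        positions=raster.positions,
        ei_label=raster.ei_label,
        neuron_ids=raster.neuron_ids,
    )
    return restricted, intervals


def _runs_from_totals(totals: np.ndarray, start_offset: int = 0) -> list[Avalanche]:
    """Maximal runs of consecutive non-empty bins in a per-bin total array."""
    occ = totals > 0
    if not occ.any():
        return []
    padded = np.concatenate(([False], occ, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    csum = np.concatenate(([0], np.cumsum(totals)))
    return [
        Avalanche(start_bin=int(s + start_offset), T=int(e - s), S=int(csum[e] - csum[s]))
        for s, e in zip(starts, ends)
    ]


def detect_avalanches(
    binned: BinnedRaster,
    boundaries: list[tuple[float, float]] | None = None,
    state: str = "all",
    patch_id: int | None = None,
) -> AvalancheSet:
    """Detect avalanches as maximal runs of non-empty bins.

    ``boundaries`` is an optional list of (start_s, end_s) intervals in
    seconds; runs are split at the bins containing interval edges so that an
    avalanche never crosses from one interval to the next.
    """
    totals = binned.bin_totals()
    if boundaries is None:
        avs = _runs_from_totals(totals)
    else:
        avs = []
        w, origin = binned.bin_width, binned.origin
        for a, b in boundaries:
            j0 = max(int(np.ceil((a - origin) / w - 1e-9)), 0)
            j1 = min(int(np.floor((b - origin) / w + 1e-9)), totals.size)
            if j1 > j0:
                avs.extend(_runs_from_totals(totals[j0:j1], start_offset=j0))
    return AvalancheSet.from_avalanches(
        avs, bin_width=binned.bin_width, state=state, patch_id=patch_id
    )


def avalanches_in_intervals(
    pooled_times: np.ndarray,
    intervals: list[tuple[float, float]],
    bin_width: float,
    state: str = "all",
    patch_id: int | None = None,
) -> AvalancheSet:
    """Fast avalanche detection from pooled sorted spike times.

    The bin grid restarts at each interval's start (avoiding heterogeneous
    partial bins), and runs are confined to single intervals.  Equivalent to
    binning each interval separately and calling :func:`detect_avalanches`,
    but without materialising per-neuron count matrices — necessary when the
    bin width is the 0.1 ms integration step of a simulation.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    all_S: list[np.ndarray] = []
    all_T: list[np.ndarray] = []
    all_B: list[np.ndarray] = []
    for a, b in intervals:
        lo = np.searchsorted(pooled_times, a, side="left")
        hi = np.searchsorted(pooled_times, b, side="left")
        if hi == lo:
            continue
        t = pooled_times[lo:hi]
        n_bins = max(int(np.ceil((b - a) / bin_width)), 1)
        j = np.minimum(np.floor((t - a) / bin_width).astype(np.int64), n_bins - 1)
        # runs of consecutive occupied bin indices
        uniq, counts = np.unique(j, return_counts=True)
        brk = np.flatnonzero(np.diff(uniq) > 1) + 1
        seg_starts = np.concatenate(([0], brk))
        seg_ends = np.concatenate((brk, [uniq.size]))
        csum = np.concatenate(([0], np.cumsum(counts)))
        all_B.append(uniq[seg_starts])
        all_T.append(uniq[seg_ends - 1] - uniq[seg_starts] + 1)
        all_S.append(csum[seg_ends] - csum[seg_starts])
    if not all_S:
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            start_bins=np.empty(0, dtype=np.int64),
            bin_width=bin_width, state=state, patch_id=patch_id,
        )
    return AvalancheSet(
        sizes=np.concatenate(all_S),
        durations=np.concatenate(all_T),
        start_bins=np.concatenate(all_B),
        bin_width=bin_width, state=state, patch_id=patch_id,
    )


def sample_patches(raster: SpikeRaster, spec: PatchSpec) -> list[SpikeRaster]:
    """Draw the patch ensemble of sub-rasters defined by ``spec``.

    Reproducible under ``spec.seed``; patches are independent of each other.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "circular":
        if raster.positions is None:
            raise ValueError("circular patch mode requires neuron positions")
        cx, cy = spec.center_um if spec.center_um is not None else raster.positions.mean(axis=0)
        d2 = (raster.positions[:, 0] - cx) ** 2 + (raster.positions[:, 1] - cy) ** 2
        pool = np.flatnonzero(d2 <= spec.radius_um**2)
    else:
        pool = np.arange(raster.n_neurons)
    if pool.size == 0:
        raise ValueError("patch pool is empty (no neurons inside the disk?)")
    k = max(int(np.floor(spec.fraction * pool.size)), 1)
    patches = []
    for pid in range(spec.n_patches):
        chosen = rng.choice(pool, size=k, replace=False) if k < pool.size else pool
        patches.append(raster.subset(np.sort(chosen)))
    return patches


def mean_duration_vs_size(
    sets: AvalancheSet | list[AvalancheSet],
    n_classes: int = 30,
    min_count: int = 10,
    min_size: int = 1,
    max_size: int | None = None,
) -> dict:
    """Fit the size-duration scaling exponent gamma from <T>(S) ~ S^gamma.

    Avalanches are pooled over the supplied sets, the conditional mean
    duration is computed in logarithmically spaced size classes, and gamma
    is the weighted least-squares slope of log<T> vs log S over classes with
    at least ``min_count`` avalanches.  Durations are measured in bins and
    sizes in spikes; the exponent is invariant to those units.

    Returns a dict with ``gamma``, its standard error from the fit
    covariance, and the class centres/means used.
    """
    if isinstance(sets, AvalancheSet):
        sets = [sets]
    S = np.concatenate([s.sizes for s in sets]) if sets else np.empty(0, dtype=np.int64)
    T = np.concatenate([s.durations for s in sets]) if sets else np.empty(0, dtype=np.int64)
    keep = S >= min_size
    if max_size is not None:
        keep &= S <= max_size
    S, T = S[keep], T[keep]
    if S.size == 0 or np.unique(S).size < 2:
        return {"gamma": np.nan, "gamma_se": np.nan, "degenerate": True}
    lo, hi = S.min(), S.max()
    edges = np.unique(np.round(np.geomspace(lo, hi + 1, n_classes + 1)).astype(np.int64))
    idx = np.digitize(S, edges) - 1
    centers, means, ns = [], [], []
    for c in range(edges.size - 1):
        sel = idx == c
        n = int(sel.sum())
        if n >= min_count:
            centers.append(np.sqrt(edges[c] * edges[c + 1]))
            means.append(T[sel].mean())
            ns.append(n)
    if len(centers) < 2:
        return {"gamma": np.nan, "gamma_se": np.nan, "degenerate": True}
    x = np.log(np.asarray(centers))
    y = np.log(np.asarray(means))
    w = np.asarray(ns, dtype=float)
    coef, cov = np.polyfit(x, y, deg=1, w=np.sqrt(w), cov="unscaled")
    # rescale covariance by residual variance for an empirical uncertainty
    resid = y - np.polyval(coef, x)
    dof = max(x.size - 2, 1)
    scale = float(np.sum(w * resid**2) / np.sum(w)) * x.size / dof
    gamma_se = float(np.sqrt(cov[0, 0] * max(scale, 1e-30)))
    return {
        "gamma": float(coef[0]),
        "gamma_se": gamma_se,
        "class_centers": np.asarray(centers),
        "class_means": np.asarray(means),
        "class_counts": np.asarray(ns),
        "degenerate": False,
    }


def isi_stats(raster: SpikeRaster, seg: StateSegmentation) -> dict:
    """Per-state mean single-cell interspike interval (seconds).

    ISIs are differences between consecutive spikes of the same neuron that
    fall inside the same state interval; pairs straddling a state transition
    are censored.  ISIs are pooled over neurons within each state.
    """
    out = {}
    for label in ("up", "down"):
        intervals = seg.intervals_of(label)
        isis: list[np.ndarray] = []
        for t in raster.spike_times:
            if t.size < 2:
                continue
            for a, b in intervals:
                inside = t[(t >= a) & (t < b)]
                if inside.size >= 2:
                    isis.append(np.diff(inside))
        if isis:
            pooled = np.concatenate(isis)
            out[label] = {
                "mean_isi_s": float(pooled.mean()),
                "n_isis": int(pooled.size),
            }
        else:
            out[label] = {"mean_isi_s": None, "n_isis": 0}
    return out
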