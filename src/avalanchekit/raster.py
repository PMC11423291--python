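"""Spike-raster data model, file I/O, and temporal binning.

A :class:`SpikeRaster` holds per-neuron spike-time lists (seconds) for a
population of recorded or simulated neurons, optionally with spatial
positions (micrometres) and excitatory/inhibitory labels.  Rasters are the
common currency of the whole pipeline: calcium-imaging spike inference and
the network simulator both produce them, and state detection and avalanche
analysis consume them.

Binning uses half-open bins ``[origin + j*w, origin + (j+1)*w)`` so that no
spike is ever counted twice; a spike exactly at ``duration`` falls in the
last covered bin.  Binned counts are stored as a sparse neuron x bin matrix
because simulated rasters binned at the integration step (0.1 ms) would be
far too large dense.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpikeRaster",
    "BinnedRaster",
    "read_spike_raster",
    "write_spike_raster",
    "bin_raster",
]


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


@dataclass
class SpikeRaster:
    """Per-neuron spike times for a neuronal population.

    Parameters
    ----------
    spike_times
        List of 1-D float arrays, one per neuron, spike times in seconds,
        strictly increasing within each neuron.
    duration
        Recording length in seconds.  Every spike must lie in
        ``[0, duration]``.
    frame_interval
        Acquisition frame (or simulation output step) in seconds; 5 ms for
        200 fps calcium imaging, the integration step for simulations.
    positions
        Optional ``(n, 2)`` array of (x, y) soma positions in micrometres.
    ei_label
        Optional length-``n`` int8 array, 0 = excitatory, 1 = inhibitory.
    neuron_ids
        Integer labels; defaults to ``0..n-1``.
    """

    spike_times: list[np.ndarray]
    duration: float
    frame_interval: float = 0.005
    positions: np.ndarray | None = None
    ei_label: np.ndarray | None = None
    neuron_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.n_neurons)
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        for i, t in enumerate(self.spike_times):
            if t.size == 0:
                continue
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError(
                    f"neuron {i}: spike times outside [0, {self.duration}]"
                )
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"neuron {i}: spike times not strictly increasing")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.n_neurons, 2):
                raise ValueError(
                    f"positions shape {self.positions.shape} != ({self.n_neurons}, 2)"
                )
        if self.ei_label is not None:
            self.ei_label = np.asarray(self.ei_label, dtype=np.int8)
            if self.ei_label.shape != (self.n_neurons,):
                raise ValueError("ei_label must have one entry per neuron")

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def pooled_times(self) -> np.ndarray:
        """All spike times merged across neurons, sorted ascending."""
        if self.n_spikes == 0:
            return np.empty(0)
        return np.sort(np.concatenate([t for t in self.spike_times if t.size]))

    def subset(self, neuron_idx: np.ndarray) -> "SpikeRaster":
        """Raster restricted to the neurons at positional indices ``neuron_idx``."""
        idx = np.asarray(neuron_idx)
        return SpikeRaster(
            spike_times=[self.spike_times[i] for i in idx],
            duration=self.duration,
            frame_interval=self.frame_interval,
            positions=None if self.positions is None else self.positions[idx],
            ei_label=None if self.ei_label is None else self.ei_label[idx],
            neuron_ids=self.neuron_ids[idx],
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat ``(neuron_index, time)`` arrays sorted by time then neuron."""
        n_sp = self.n_spikes
        nid = np.empty(n_sp, dtype=np.int64)
        ts = np.empty(n_sp, dtype=float)
        k = 0
        for i, t in enumerate(self.spike_times):
            nid[k : k + t.size] = i
            ts[k : k + t.size] = t
            k += t.size
        order = np.lexsort((nid, ts))
        return nid[order], ts[order]


@dataclass
class BinnedRaster:
    """Spike counts on a regular half-open bin grid.

    ``counts`` is a sparse CSR matrix of shape (n_neurons, n_bins); the sum
    of all entries equals the number of source-raster spikes falling in
    ``[origin, origin + n_bins * bin_width)``.
    """

    counts: sp.csr_matrix
    bin_width: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        self.counts = sp.csr_matrix(self.counts)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def bin_totals(self) -> np.ndarray:
        """Population spike count per bin (1-D array of length n_bins)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()


def bin_raster(
    raster: SpikeRaster,
    bin_width: float,
    origin: float = 0.0,
    n_bins: int | None = None,
) -> BinnedRaster:
    """Bin a spike raster on the half-open grid ``[origin + j*w, origin + (j+1)*w)``.

    The grid covers ``[origin, raster.duration]`` by default so that a spike
    exactly at ``duration`` lands in the final bin; total spike count within
    the covered window is conserved.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if n_bins is None:
        n_bins = int(np.ceil((raster.duration - origin) / bin_width))
        # a spike exactly at duration must land inside the grid
        if origin + n_bins * bin_width <= raster.duration:
            n_bins += 1
        n_bins = max(n_bins, 1)
    rows, cols = [], []
    for i, t in enumerate(raster.spike_times):
        j = np.floor((t - origin) / bin_width).astype(np.int64)
        ok = (j >= 0) & (j < n_bins)
        rows.append(np.full(int(ok.sum()), i, dtype=np.int64))
        cols.append(j[ok])
    rows_a = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols_a = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    counts = sp.csr_matrix(
        (np.ones(rows_a.size, dtype=np.int64), (rows_a, cols_a)),
        shape=(raster.n_neurons, n_bins),
    )
    return BinnedRaster(counts=counts, bin_width=bin_width, origin=origin)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_header(lines: list[str]) -> dict:
    meta: dict = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    return meta


def _read_delimited(path: Path) -> SpikeRaster:
    header_lines: list[str] = []
    data_lines: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            s = ln.strip()
            if not s:
                continue
            if s.startswith("#"):
                header_lines.append(s)
            else:
                data_lines.append((lineno, s))
    meta = _parse_header(header_lines)
    # skip a textual column header like "neuron_id,time_s"
    if data_lines:
        first = data_lines[0][1]
        token = first.replace(",", " ").replace("\t", " ").split()[0]
        try:
            float(token)
        except ValueError:
            data_lines = data_lines[1:]
    ids = np.empty(len(data_lines), dtype=np.int64)
    times = np.empty(len(data_lines), dtype=float)
    for k, (lineno, s) in enumerate(data_lines):
        parts = [p for p in s.replace(",", " ").replace("\t", " ").split() if p]
        if len(parts) < 2:
            raise RasterFormatError(f"{path}:{lineno}: expected 2 columns, got {s!r}")
        try:
            ids[k] = int(float(parts[0]))
            times[k] = float(parts[1])
        except ValueError as exc:
            raise RasterFormatError(f"{path}:{lineno}: malformed row {s!r}") from exc
    if times.size and times.min() < 0:
        raise ValueError(f"{path}: negative spike times")
    n_neurons = int(meta.get("n_neurons", ids.max() + 1 if ids.size else 0))
    if n_neurons <= 0:
        raise RasterFormatError(f"{path}: empty file with no n_neurons header")
    duration = float(meta.get("duration", times.max() if times.size else 1.0))
    frame_interval = float(meta.get("frame_interval", 0.005))
    spike_times = [np.sort(times[ids == i]) for i in range(n_neurons)]
    return SpikeRaster(
        spike_times=spike_times,
        duration=duration,
        frame_interval=frame_interval,
    )


def _read_hdf5(path: Path) -> SpikeRaster:
    with h5py.File(path, "r") as fh:
        ids = fh["/spikes/neuron_id"][...].astype(np.int64)
        times = fh["/spikes/time_s"][...].astype(float)
        n_neurons = int(fh.attrs["n_neurons"])
        duration = float(fh.attrs["duration_s"])
        frame_interval = float(fh.attrs.get("frame_interval_s", 0.005))
        positions = fh["/positions"][...] if "positions" in fh else None
        ei_label = fh["/ei_label"][...] if "ei_label" in fh else None
    spike_times = [np.sort(times[ids == i]) for i in range(n_neurons)]
    return SpikeRaster(
        spike_times=spike_times,
        duration=duration,
        frame_interval=frame_interval,
        positions=positions,
        ei_label=ei_label,
    )


def read_spike_raster(path: str | Path, format: str | None = None) -> SpikeRaster:
    """Read a spike raster from a delimited text file or an HDF5 file.

    The delimited dialect is two columns ``neuron_id, time_s`` (comma, tab
    or whitespace separated) with optional ``#``-prefixed header lines
    carrying ``n_neurons``, ``duration`` and ``frame_interval``.  The HDF5
    layout is ``/spikes/neuron_id``, ``/spikes/time_s`` plus root attributes
    ``n_neurons``, ``duration_s``, ``frame_interval_s`` and optional
    ``/positions`` and ``/ei_label`` datasets.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "delimited"
    if format == "delimited":
        return _read_delimited(path)
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def write_spike_raster(
    raster: SpikeRaster, path: str | Path, format: str | None = None
) -> None:
    """Write a raster so that :func:`read_spike_raster` round-trips it."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "delimited"
    if format == "delimited":
        buf = io.StringIO()
        buf.write(f"# n_neurons = {raster.n_neurons}\n")
        buf.write(f"# duration = {raster.duration!r}\n")
        buf.write(f"# frame_interval = {raster.frame_interval!r}\n")
        nid, ts = raster.to_arrays()
        for i, t in zip(nid, ts):
            buf.write(f"{i},{float(t)!r}\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif format == "hdf5":
        nid, ts = raster.to_arrays()
        with h5py.File(path, "w") as fh:
            fh.create_dataset("/spikes/neuron_id", data=nid)
            fh.create_dataset("/spikes/time_s", data=ts)
            fh.attrs["n_neurons"] = raster.n_neurons
            fh.attrs["duration_s"] = raster.duration
            fh.attrs["frame_interval_s"] = raster.frame_interval
            if raster.positions is not None:
                fh.create_dataset("/positions", data=raster.positions)
            if raster.ei_label is not None:
                fh.create_dataset("/ei_label", data=raster.ei_label)
    else:
        raise ValueError(f"unknown format {format!r}")
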