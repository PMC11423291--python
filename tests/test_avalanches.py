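import numpy as np
import pytest

from avalanchekit.avalanches import (
    Avalanche,
    AvalancheSet,
    PatchSpec,
    avalanches_in_intervals,
    detect_avalanches,
    isi_stats,
    mean_duration_vs_size,
    restrict_to_state,
    sample_patches,
)
from avalanchekit.raster import BinnedRaster, SpikeRaster, bin_raster
from avalanchekit.states import StateSegmentation

from conftest import make_poisson_raster


def binned_from_totals(totals, bin_width=0.005):
    import scipy.sparse as sp

    counts = sp.csr_matrix(np.asarray(totals, dtype=np.int64)[None, :])
    return BinnedRaster(counts=counts, bin_width=bin_width)


def seg_from_intervals(intervals):
    t_up = [e - s for s, e, l in intervals[1:-1] if l == "up"]
    t_down = [e - s for s, e, l in intervals[1:-1] if l == "down"]
    return StateSegmentation(intervals=intervals, t_up=t_up, t_down=t_down)


class TestDetection:
    def test_forced_example(self):
        aset = detect_avalanches(binned_from_totals([0, 2, 1, 0, 0, 3, 0]))
        assert [(a.S, a.T) for a in aset.avalanches] == [(3, 2), (3, 1)]

    def test_single_run(self):
        aset = detect_avalanches(binned_from_totals([1, 1, 1, 1]))
        assert [(a.S, a.T) for a in aset.avalanches] == [(4, 4)]

    def test_empty_input(self):
        aset = detect_avalanches(binned_from_totals([0, 0, 0]))
        assert len(aset) == 0

    def test_boundaries_split_runs(self):
        # continuous activity, but an interval edge at 3 bins splits the run
        aset = detect_avalanches(
            binned_from_totals([1, 1, 1, 1, 1, 1]),
            boundaries=[(0.0, 0.015), (0.015, 0.030)],
        )
        assert sorted((a.S, a.T) for a in aset.avalanches) == [(3, 3), (3, 3)]

    def test_invariants_on_random_rasters(self, rng):
        raster = make_poisson_raster(20, 10.0, 6.0, rng)
        pooled = raster.pooled_times()
        aset = avalanches_in_intervals(pooled, [(0.0, raster.duration)], 0.01)
        assert aset.total_spikes == raster.n_spikes  # conservation
        assert np.all(aset.sizes >= aset.durations)
        assert np.all(aset.durations >= 1)

    def test_count_non_increasing_under_bin_doubling(self, rng):
        raster = make_poisson_raster(15, 10.0, 4.0, rng)
        pooled = raster.pooled_times()
        counts = []
        for w in (0.002, 0.004, 0.008, 0.016):
            counts.append(len(avalanches_in_intervals(pooled, [(0.0, 10.0)], w)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_matches_binned_path(self, rng):
        """Sparse-times path and dense binned-matrix path agree."""
        raster = make_poisson_raster(8, 4.0, 5.0, rng)
        w = 0.01
        via_times = avalanches_in_intervals(
            raster.pooled_times(), [(0.0, raster.duration)], w
        )
        n_bins = int(np.ceil(raster.duration / w))
        via_binned = detect_avalanches(bin_raster(raster, w, n_bins=n_bins))
        assert sorted(zip(via_times.sizes, via_times.durations)) == sorted(
            zip(via_binned.sizes, via_binned.durations)
        )

    def test_invalid_avalanche_rejected(self):
        with pytest.raises(ValueError):
            Avalanche(start_bin=0, T=3, S=2)


class TestStateRestriction:
    def test_all_up_is_identity(self, poisson_raster):
        seg = seg_from_intervals([(0.0, poisson_raster.duration, "up")])
        restricted, intervals = restrict_to_state(poisson_raster, seg, "up")
        assert restricted.n_spikes == poisson_raster.n_spikes
        assert intervals == [(0.0, poisson_raster.duration)]

    def test_missing_label_warns_empty(self, poisson_raster):
        seg = seg_from_intervals([(0.0, poisson_raster.duration, "down")])
        with pytest.warns(UserWarning):
            restricted, _ = restrict_to_state(poisson_raster, seg, "up")
        assert restricted.n_spikes == 0

    def test_against_brute_force_membership(self, rng):
        raster = make_poisson_raster(10, 12.0, 2.0, rng)
        intervals = [
            (0.0, 2.0, "down"), (2.0, 3.0, "up"), (3.0, 7.0, "down"),
            (7.0, 7.5, "up"), (7.5, 12.0, "down"),
        ]
        seg = seg_from_intervals(intervals)
        restricted, _ = restrict_to_state(raster, seg, "up")
        expected = 0
        for t in raster.spike_times:
            for s, e, lab in intervals:
                if lab == "up":
                    expected += int(np.sum((t >= s) & (t < e)))
        assert restricted.n_spikes == expected


class TestPatches:
    def test_full_fraction_is_identity(self, poisson_raster):
        patches = sample_patches(poisson_raster, PatchSpec(fraction=1.0, n_patches=1))
        assert patches[0].n_neurons == poisson_raster.n_neurons

    def test_patch_size(self, rng):
        raster = make_poisson_raster(100, 1.0, 1.0, rng)
        patches = sample_patches(raster, PatchSpec(fraction=0.5, n_patches=7, seed=3))
        assert all(p.n_neurons == 50 for p in patches)

    def test_seed_determinism(self, poisson_raster):
        spec = PatchSpec(fraction=0.5, n_patches=5, seed=11)
        a = sample_patches(poisson_raster, spec)
        b = sample_patches(poisson_raster, spec)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.neuron_ids, pb.neuron_ids)

    def test_circular_requires_positions(self, poisson_raster):
        with pytest.raises(ValueError):
            sample_patches(
                poisson_raster,
                PatchSpec(mode="circular", radius_um=100.0, n_patches=1),
            )

    def test_circular_restricts_to_disk(self, rng):
        raster = make_poisson_raster(200, 1.0, 1.0, rng, positions=True)
        spec = PatchSpec(mode="circular", radius_um=300.0,
                         center_um=(500.0, 500.0), fraction=1.0, n_patches=1)
        patch = sample_patches(raster, spec)[0]
        d = np.hypot(patch.positions[:, 0] - 500.0, patch.positions[:, 1] - 500.0)
        assert np.all(d <= 300.0)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            PatchSpec(fraction=0.0)

    def test_pooled_histogram_is_sum_of_patches(self, rng):
        raster = make_poisson_raster(30, 5.0, 5.0, rng)
        patches = sample_patches(raster, PatchSpec(fraction=0.5, n_patches=4, seed=2))
        sets = [
            avalanches_in_intervals(p.pooled_times(), [(0.0, 5.0)], 0.01, patch_id=i)
            for i, p in enumerate(patches)
        ]
        pooled = sets[0]
        for s in sets[1:]:
            pooled = pooled.merged_with(s)
        per_patch = sum((np.bincount(s.sizes, minlength=200) for s in sets),
                        np.zeros(200, dtype=int))
        np.testing.assert_array_equal(
            np.bincount(pooled.sizes, minlength=200), per_patch
        )


class TestGamma:
    def _aset(self, S, T):
        return AvalancheSet(
            sizes=np.asarray(S), durations=np.asarray(T),
            start_bins=np.zeros(len(S), dtype=int), bin_width=1.0,
        )

    def test_exact_square_root_scaling(self, rng):
        S = rng.integers(1, 10_000, 5000)
        T = np.maximum(np.round(S**0.5), 1).astype(int)
        S = np.maximum(S, T)  # keep S >= T
        out = mean_duration_vs_size(self._aset(S, T), min_size=10)
        assert out["gamma"] == pytest.approx(0.5, abs=0.02)

    def test_identity_scaling(self, rng):
        S = rng.integers(1, 1000, 3000)
        out = mean_duration_vs_size(self._aset(S, S))
        assert out["gamma"] == pytest.approx(1.0, abs=0.02)

    def test_degenerate_flagged(self):
        out = mean_duration_vs_size(self._aset([5] * 10, [2] * 10))
        assert out["degenerate"]
        assert np.isnan(out["gamma"])


class TestISI:
    def test_constant_isi_within_one_interval(self):
        times = np.arange(0.05, 0.95, 0.1)
        raster = SpikeRaster(spike_times=[times], duration=1.0)
        seg = seg_from_intervals([(0.0, 1.0, "up")])
        out = isi_stats(raster, seg)
        assert out["up"]["mean_isi_s"] == pytest.approx(0.1)
        assert out["down"]["n_isis"] == 0

    def test_no_isi_bridges_state_gap(self):
        # two spikes in separate up intervals: no ISI at all
        raster = SpikeRaster(spike_times=[np.array([0.5, 2.5])], duration=3.0)
        seg = seg_from_intervals(
            [(0.0, 1.0, "up"), (1.0, 2.0, "down"), (2.0, 3.0, "up")]
        )
        out = isi_stats(raster, seg)
        assert out["up"]["n_isis"] == 0

    def test_pooling_over_neurons(self):
        raster = SpikeRaster(
            spike_times=[np.array([0.1, 0.2]), np.array([0.1, 0.4])], duration=1.0
        )
        seg = seg_from_intervals([(0.0, 1.0, "up")])
        out = isi_stats(raster, seg)
        assert out["up"]["n_isis"] == 2
        assert out["up"]["mean_isi_s"] == pytest.approx(0.2)
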