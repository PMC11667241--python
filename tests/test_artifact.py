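"""Intensity normalization, pseudo-average binning, denoiser training."""

import numpy as np
import pytest

from moco4d.artifact import (
    ArtifactReducer,
    DenoiserConfig,
    DenoiserNet,
    build_pseudo_average_bins,
    make_training_pairs,
    normalize_intensity,
)
from moco4d.fdk import PhaseImageSet, fdk_reconstruct, reconstruct_phase_images
from moco4d.geometry import GridSpec, Volume
from moco4d.respiratory import PhaseBinning


def synthetic_binning(n_phases=10, n_cycles=15, per_phase=1):
    """Uniformly sampled binning with explicit cycle indices."""
    labels = np.tile(np.repeat(np.arange(n_phases), per_phase), n_cycles)
    cycles = np.repeat(np.arange(n_cycles), n_phases * per_phase)
    fractions = (labels + 0.5) / n_phases
    return PhaseBinning(n_phases, fractions, labels, cycle_index=cycles)


class TestNormalize:
    def grid(self, shape=(6, 6, 6)):
        return GridSpec(shape=shape, spacing=(1.0, 1.0, 1.0))

    def test_constant_volume_warns_and_zeroes(self):
        vol = Volume(np.full((6, 6, 6), 3.0), self.grid())
        with pytest.warns(UserWarning, match="constant"):
            out, norm = normalize_intensity(vol)
        assert np.all(out.data == 0.0)

    def test_output_spans_unit_range(self):
        rng = np.random.default_rng(0)
        vol = Volume(rng.random((8, 8, 8)), self.grid((8, 8, 8)))
        out, norm = normalize_intensity(vol)
        assert out.data.min() == 0.0
        assert out.data.max() == 1.0
        assert out.kind == "normalized"

    def test_round_trip_identity_on_clipped_values(self):
        rng = np.random.default_rng(1)
        data = rng.random((8, 8, 8))
        vol = Volume(data, self.grid((8, 8, 8)))
        out, norm = normalize_intensity(vol)
        clipped = np.clip(data, norm.lo, norm.hi)
        np.testing.assert_allclose(norm.invert(out.data), clipped, atol=1e-6)


class TestPseudoAverageBins:
    def test_every_pseudo_bin_mixes_all_phases(self):
        binning = synthetic_binning(n_phases=10, n_cycles=15)
        pseudo = build_pseudo_average_bins(binning)
        for b in range(10):
            members = pseudo.members(b)
            source_phases = set(binning.labels[members])
            assert source_phases == set(range(10))

    def test_partition_property(self):
        binning = synthetic_binning(n_phases=6, n_cycles=5, per_phase=3)
        pseudo = build_pseudo_average_bins(binning)
        assert pseudo.bin_sizes().sum() == len(binning.labels)
        assert pseudo.kind == "pseudo-average"
        # disjoint by construction: each projection has exactly one label
        assert len(pseudo.labels) == len(binning.labels)

    def test_size_distribution_matches_phase_bins_up_to_permutation(self):
        binning = synthetic_binning(n_phases=8, n_cycles=7, per_phase=2)
        pseudo = build_pseudo_average_bins(binning)
        assert sorted(pseudo.bin_sizes()) == sorted(binning.bin_sizes())

    def test_provenance_records_cycle_and_phase(self):
        binning = synthetic_binning(n_phases=4, n_cycles=3)
        pseudo = build_pseudo_average_bins(binning)
        for b, entries in pseudo.provenance.items():
            assert all((b + c) % 4 == p for c, p in entries)
            assert len({p for _, p in entries}) >= 2

    def test_single_cycle_rejected(self):
        binning = synthetic_binning(n_phases=4, n_cycles=1)
        with pytest.raises(ValueError, match="single cycle"):
            build_pseudo_average_bins(binning)

    def test_missing_cycle_index_rejected(self):
        binning = PhaseBinning(2, np.zeros(4), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="cycle"):
            build_pseudo_average_bins(binning)


class TestTrainingPairs:
    def test_pair_count_and_streaks(self, scan, binning4, small_grid):
        pairs, norm = make_training_pairs(scan, binning4, grid=small_grid)
        assert len(pairs) == binning4.n_bins
        for inp, tgt in pairs:
            assert inp.data.shape == tgt.data.shape
            # undersampling streaks: input differs from the target
            assert np.sqrt(np.mean((inp.data - tgt.data) ** 2)) > 0

    def test_pseudo_average_centroid_matches_time_average(
            self, scan, binning4, small_grid, phantom, breathing):
        """Pseudo-average inputs carry time-averaged motion, unlike a real
        phase bin whose tumor sits at the phase position."""
        pairs, norm = make_training_pairs(scan, binning4, grid=small_grid)
        target = pairs[0][1]
        xx, yy, zz = small_grid.world_coordinates()
        c = phantom.tumor.center
        near = ((xx - c[0]) ** 2 + (yy - c[1]) ** 2
                + (zz - c[2]) ** 2) < 40.0**2

        def centroid(data, thr):
            m = (data > thr) & near
            assert m.sum() > 0
            return np.array([(xx * m).sum(), (yy * m).sum(),
                             (zz * m).sum()]) / m.sum()

        thr = np.percentile(target.data[near], 90)
        c_target = centroid(target.data, thr)
        voxel = max(small_grid.spacing)
        for inp, _ in pairs:
            c_inp = centroid(inp.data, thr)
            assert np.linalg.norm(c_inp - c_target) < 1.5 * voxel


class TestDenoiser:
    def identity_pairs(self, n=2, shape=(12, 12, 12)):
        rng = np.random.default_rng(0)
        vols = [rng.random(shape).astype(np.float32) for _ in range(n)]
        return [(v, v) for v in vols]

    def test_identity_task_is_learnable(self):
        """The residual net starts at the identity and stays there."""
        cfg = DenoiserConfig(base_channels=4, epochs=15, seed=0)
        res = ArtifactReducer(self.identity_pairs(), cfg).fit()
        assert res.loss_trace[-1] <= res.loss_trace[0]
        assert res.loss_trace[-1] < 1e-3

    def test_denoising_task_reduces_loss(self):
        """Noisy-input/clean-target training drives the loss down."""
        rng = np.random.default_rng(3)
        clean = rng.random((12, 12, 12)).astype(np.float32)
        noisy = clean + 0.3 * rng.normal(size=clean.shape).astype(np.float32)
        cfg = DenoiserConfig(base_channels=4, epochs=45, learning_rate=5e-3,
                             seed=0)
        res = ArtifactReducer([(noisy, clean)], cfg).fit()
        assert res.loss_trace[-1] < 0.5 * res.loss_trace[0]

    def test_training_is_seeded_deterministic(self):
        cfg = DenoiserConfig(base_channels=4, epochs=3, seed=5)
        r1 = ArtifactReducer(self.identity_pairs(), cfg).fit()
        r2 = ArtifactReducer(self.identity_pairs(), cfg).fit()
        for (k1, p1), (k2, p2) in zip(r1.network.named_parameters(),
                                      r2.network.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_untrained_network_is_identity(self):
        net = DenoiserNet(DenoiserConfig(base_channels=4))
        img = np.random.default_rng(2).random((10, 11, 9)).astype(np.float32)
        np.testing.assert_allclose(net(img).data, img, atol=1e-7)

    def test_apply_preserves_geometry_and_handles_zero_input(self):
        grid = GridSpec(shape=(12, 12, 12), spacing=(2.0, 2.0, 2.0))
        cfg = DenoiserConfig(base_channels=4, epochs=2, seed=0)
        res = ArtifactReducer(self.identity_pairs(), cfg).fit()
        images = PhaseImageSet([
            Volume(np.zeros((12, 12, 12)), grid, kind="normalized"),
            Volume(np.random.default_rng(0).random((12, 12, 12)), grid,
                   kind="normalized"),
        ])
        out = res.apply(images)
        assert out.n_phases == 2
        for vin, vout in zip(images.volumes, out.volumes):
            assert vout.data.shape == vin.data.shape
            assert vout.grid.spacing == vin.grid.spacing
            assert np.all(np.isfinite(vout.data))

    def test_streak_energy_reduced_on_simulated_phases(
            self, scan, binning4, small_grid, gt_phase_volumes):
        """Denoising moves 4D-FDK phase images toward the ground truth."""
        pairs, norm = make_training_pairs(scan, binning4, grid=small_grid)
        cfg = DenoiserConfig(base_channels=8, epochs=20, seed=0)
        res = ArtifactReducer(pairs, cfg).fit()
        fdk4d = reconstruct_phase_images(scan, binning4, grid=small_grid)
        normalized = PhaseImageSet([
            v.copy_with(norm.apply(v.data), kind="normalized")
            for v in fdk4d.volumes
        ])
        reduced = res.apply(normalized)
        improved = 0
        for b in range(binning4.n_bins):
            gt = norm.apply(gt_phase_volumes.volumes[b].data)
            before = np.sqrt(np.mean((normalized.volumes[b].data - gt) ** 2))
            after = np.sqrt(np.mean((reduced.volumes[b].data - gt) ** 2))
            improved += after < before
        assert improved >= 3  # at least 3 of 4 phases improve

    def test_non_finite_loss_aborts(self):
        bad = [(np.full((8, 8, 8), np.inf, dtype=np.float32),
                np.zeros((8, 8, 8), dtype=np.float32))]
        cfg = DenoiserConfig(base_channels=2, epochs=1)
        with pytest.raises(FloatingPointError):
            ArtifactReducer(bad, cfg).fit()

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            ArtifactReducer([], DenoiserConfig())
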