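"""Phantom, breathing model, ground-truth fields, landmarks, scan simulation."""

import numpy as np
import pytest

from moco4d.geometry import ConeBeamGeometry, GridSpec, Volume
from moco4d.phantom import (
    Cylinder,
    Ellipsoid,
    PhantomSpec,
    Sphere,
    breathing_trace,
    default_breathing,
    default_phantom,
    ground_truth_dvf,
    phantom_landmarks,
    phantom_family,
    rasterize_phantom,
    simulate_scan,
)
from moco4d.projections import forward_project
from moco4d.transforms import warp_array


def tumor_centroid(volume, spec, grid, radius_mm=32.0):
    """Centroid of tumor-attenuation voxels near the reference tumor."""
    xx, yy, zz = grid.world_coordinates()
    c = spec.tumor.center
    near = ((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
            < radius_mm**2)
    m = (volume.data > 0.023) & (volume.data < 0.035) & near
    assert m.sum() > 0
    return np.array([(xx * m).sum(), (yy * m).sum(), (zz * m).sum()]) / m.sum()


class TestRasterize:
    def test_phase_zero_equals_static_reference(self, phantom, breathing,
                                                small_grid):
        moving = rasterize_phantom(phantom, breathing, 0.0, small_grid)
        xx, yy, zz = small_grid.world_coordinates()
        static = phantom.attenuation(xx, yy, zz)
        np.testing.assert_allclose(moving.data, static, atol=1e-12)

    def test_zero_attenuation_phantom_rasterizes_to_zero(self, small_grid):
        spec = PhantomSpec(
            body=Ellipsoid((0, 0, 0), (100, 80, 80), 0.0),
            lungs=(Ellipsoid((-50, 0, 0), (40, 50, 60), 0.0),),
            tumor=Sphere((-50, 0, 0), 10.0, 0.0),
            diaphragm_domes=(), vessels=(), rib_mu=0.0,
        )
        vol = rasterize_phantom(spec, default_breathing(spec=spec), 0.3,
                                small_grid)
        assert np.all(vol.data == 0.0)

    def test_negative_attenuation_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            PhantomSpec(
                body=Ellipsoid((0, 0, 0), (100, 80, 80), -0.01),
                lungs=(), tumor=Sphere((0, 0, 0), 5, 0.01),
                diaphragm_domes=(), vessels=(),
            )

    def test_structure_outside_grid_warns(self, phantom, breathing):
        tiny = GridSpec(shape=(8, 8, 8), spacing=(4.0, 4.0, 4.0))
        with pytest.warns(UserWarning, match="clipped"):
            rasterize_phantom(phantom, breathing, 0.0, tiny)

    def test_tumor_centroid_tracks_analytic_displacement(
            self, phantom, breathing, small_grid):
        ref = rasterize_phantom(phantom, breathing, 0.0, small_grid,
                                supersample=2)
        moved = rasterize_phantom(phantom, breathing, 0.5, small_grid,
                                  supersample=2)
        shift = (tumor_centroid(moved, phantom, small_grid)
                 - tumor_centroid(ref, phantom, small_grid))
        predicted = breathing.displacement(np.array(phantom.tumor.center), 0.5)
        half_voxel = max(small_grid.spacing) / 2
        assert np.linalg.norm(shift - predicted) < 2 * half_voxel
        # dominant (superior-inferior) component agrees within half a voxel
        assert abs(shift[2] - predicted[2]) < half_voxel

    def test_lagrangian_consistency_with_ground_truth_dvf(
            self, phantom, breathing, small_grid):
        """Warping the reference by D(phase->0) reproduces the phase volume."""
        phase = 0.5
        ref = rasterize_phantom(phantom, breathing, 0.0, small_grid,
                                supersample=2)
        moved = rasterize_phantom(phantom, breathing, phase, small_grid,
                                  supersample=2)
        dvf = ground_truth_dvf(phantom, breathing, phase, 0.0, small_grid)
        warped = warp_array(ref.data, dvf)
        rng_att = ref.data.max() - ref.data.min()
        assert np.mean(np.abs(warped - moved.data)) < 0.02 * rng_att


class TestGroundTruthDvf:
    def test_same_phase_gives_zero_field(self, phantom, breathing, small_grid):
        d = ground_truth_dvf(phantom, breathing, 0.3, 0.3, small_grid)
        assert np.all(d == 0.0)

    def test_inverse_consistency(self, phantom, breathing, small_grid):
        from moco4d.transforms import compose_transforms

        d_ij = ground_truth_dvf(phantom, breathing, 0.0, 0.5, small_grid)
        d_ji = ground_truth_dvf(phantom, breathing, 0.5, 0.0, small_grid)
        resid = compose_transforms(d_ji, d_ij)
        xx, yy, zz = small_grid.world_coordinates()
        interior = phantom.body.inside(xx, yy, zz)
        assert np.abs(resid[:, interior]).max() < 0.1

    def test_known_point_displacement_magnitude(self, phantom, breathing,
                                                small_grid):
        """At a probe point the displacement is |a_j - a_i| * A * |u|."""
        d = ground_truth_dvf(phantom, breathing, 0.0, 0.5, small_grid)
        probe_vox = (12, 16, 22)  # inside the right lung region
        xx, yy, zz = small_grid.world_coordinates()
        p = np.array([xx[probe_vox], yy[probe_vox], zz[probe_vox]])
        expected = breathing.displacement(p, 0.5)
        got_mm = d[:, probe_vox[0], probe_vox[1], probe_vox[2]] * np.asarray(
            small_grid.spacing
        )
        np.testing.assert_allclose(got_mm, expected, atol=0.2)


class TestLandmarks:
    def test_zero_points(self, phantom, breathing, small_grid):
        a, b = phantom_landmarks(phantom, breathing, 0, 0.0, 0.5, small_grid)
        assert a.shape == (0, 3) and b.shape == (0, 3)

    def test_pair_distance_matches_analytic_motion(self, phantom, breathing,
                                                   small_grid):
        a, b = phantom_landmarks(phantom, breathing, 60, 0.1, 0.5, small_grid,
                                 seed=7)
        mm = (b - a) * np.asarray(small_grid.spacing)
        d = np.linalg.norm(mm, axis=1)
        # reconstruct expected per-point magnitude from reference positions
        da = float(breathing.a(0.5) - breathing.a(0.1)) * breathing.amplitude_mm
        pos_i = a * np.asarray(small_grid.spacing) + np.asarray(
            small_grid.origin)
        # |u| at the phase-i position approximates |u| at the reference point
        w = breathing.weight(pos_i[:, 0], pos_i[:, 1], pos_i[:, 2])
        np.testing.assert_allclose(d, np.abs(da) * w, atol=0.35)

    def test_seeded_determinism(self, phantom, breathing, small_grid):
        a1, b1 = phantom_landmarks(phantom, breathing, 20, 0.0, 0.5,
                                   small_grid, seed=3)
        a2, b2 = phantom_landmarks(phantom, breathing, 20, 0.0, 0.5,
                                   small_grid, seed=3)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_no_lung_in_grid_raises(self, phantom, breathing):
        corner = GridSpec(shape=(4, 4, 4), spacing=(2.0, 2.0, 2.0),
                          origin=(500.0, 500.0, 500.0))
        with pytest.raises(ValueError, match="lung"):
            phantom_landmarks(phantom, breathing, 5, 0.0, 0.5, corner)


class TestBreathingTrace:
    def test_fifteen_cycles_in_one_minute(self):
        t15 = breathing_trace(60.0, 4.0)
        # each completed cycle wraps the motion phase once; the cycle in
        # progress at t=0 counts as the first
        wraps = np.sum(np.diff(t15.motion_phase()) < 0)
        assert wraps + 1 == 15

    def test_seventeen_cycles_in_one_minute(self):
        trace = breathing_trace(60.0, 60.0 / 17.0)
        wraps = np.sum(np.diff(trace.motion_phase()) < 0)
        assert wraps + 1 == 17

    def test_noiseless_trace_exactly_periodic(self):
        trace = breathing_trace(20.0, 4.0, sample_rate_hz=25.0, noise_sd=0.0)
        n_period = int(4.0 * 25.0)
        s = trace.amplitude
        assert np.max(np.abs(s[:-n_period] - s[n_period:])) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            breathing_trace(-1.0, 4.0)


class TestSimulateScan:
    def test_zero_phantom_projects_to_zero(self, small_geometry, small_grid):
        spec = PhantomSpec(
            body=Ellipsoid((0, 0, 0), (100, 80, 80), 0.0),
            lungs=(), tumor=Sphere((0, 0, 0), 5, 0.0),
            diaphragm_domes=(), vessels=(), rib_mu=0.0,
        )
        br = default_breathing(spec=spec)
        trace = breathing_trace(10.0, 4.0)
        proj = simulate_scan(spec, br, trace, small_geometry,
                             n_projections=12, grid=small_grid)
        assert np.all(proj.data == 0.0)

    def test_chord_length_oracle_uniform_cylinder(self, small_geometry):
        """Central ray through a static uniform cylinder: integral = 2 r mu."""
        grid = GridSpec(shape=(24, 32, 32), spacing=(8.0, 8.0, 8.0))
        cyl = Cylinder((0, 0, 0), (0, 0, 1), 50.0, 200.0, 0.02)
        xx, yy, zz = grid.world_coordinates()
        vol = Volume(np.where(cyl.inside(xx, yy, zz), 0.02, 0.0), grid)
        proj = forward_project(vol, small_geometry, angles=[0.0])
        central = proj[0, small_geometry.n_v // 2,
                       small_geometry.n_u // 2 - 1:small_geometry.n_u // 2 + 1]
        # voxel discretization perturbs the chord by up to ~2 voxels
        assert np.all(np.abs(central - 2 * 50.0 * 0.02) < 2 * 8.0 * 0.02)

    def test_same_seed_bit_identical(self, phantom, breathing, small_geometry,
                                     small_grid):
        trace = breathing_trace(20.0, 4.0)
        kw = dict(n_projections=8, photons_i0=1e5, grid=small_grid,
                  seed=11)
        p1 = simulate_scan(phantom, breathing, trace, small_geometry, **kw)
        p2 = simulate_scan(phantom, breathing, trace, small_geometry, **kw)
        assert np.array_equal(p1.data, p2.data)

    def test_noise_variance_scales_with_photon_count(
            self, phantom, breathing, small_geometry, small_grid):
        trace = breathing_trace(10.0, 4.0)
        clean = simulate_scan(phantom, breathing, trace, small_geometry,
                              n_projections=4, grid=small_grid)
        var = {}
        for i0 in (1e5, 2e5):
            resid = []
            for seed in range(6):
                noisy = simulate_scan(phantom, breathing, trace,
                                      small_geometry, n_projections=4,
                                      photons_i0=i0, grid=small_grid,
                                      seed=seed)
                resid.append(noisy.data - clean.data)
            resid = np.concatenate([r.ravel() for r in resid])
            assert abs(resid.mean()) < 5e-4
            var[i0] = resid.var()
        ratio = var[1e5] / var[2e5]
        assert abs(ratio - 2.0) < 0.4  # halved variance at doubled photons

    def test_invalid_photon_count_rejected(self, phantom, breathing,
                                           small_geometry, small_grid):
        trace = breathing_trace(10.0, 4.0)
        with pytest.raises(ValueError, match="positive"):
            simulate_scan(phantom, breathing, trace, small_geometry,
                          n_projections=4, photons_i0=0.0, grid=small_grid)


def test_phantom_family_is_deterministic_and_valid():
    fam1 = phantom_family(3, seed=5)
    fam2 = phantom_family(3, seed=5)
    for (s1, b1), (s2, b2) in zip(fam1, fam2):
        assert s1.tumor == s2.tumor
        assert b1.amplitude_mm == b2.amplitude_mm
        assert 0 < s1.lungs[0].mu < s1.body.mu < s1.rib_mu
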