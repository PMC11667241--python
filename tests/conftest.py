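"""Shared reduced-scale fixtures: phantom, scan simulation, binning."""

import numpy as np
import pytest

from moco4d.fdk import PhaseImageSet
from moco4d.geometry import ConeBeamGeometry, GridSpec
from moco4d.phantom import (
    breathing_trace,
    default_breathing,
    default_phantom,
    rasterize_phantom,
    simulate_scan,
)
from moco4d.respiratory import bin_motion_phase, extract_respiratory_signal, phase_bin


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(shape=(24, 32, 32), spacing=(8.0, 8.0, 8.0))


@pytest.fixture(scope="session")
def small_geometry():
    return ConeBeamGeometry(sid=1000.0, sdd=1500.0, n_u=48, n_v=40,
                            du=9.0, dv=9.0)


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def breathing(phantom):
    return default_breathing(amplitude_mm=8.0, period_s=4.0, spec=phantom)


@pytest.fixture(scope="session")
def trace():
    return breathing_trace(duration_s=60.0, period_s=4.0, seed=1)


@pytest.fixture(scope="session")
def scan(phantom, breathing, trace, small_geometry, small_grid):
    """Noiseless 180-projection scan of the breathing phantom."""
    return simulate_scan(phantom, breathing, trace, small_geometry,
                         n_projections=180, seed=1, grid=small_grid)


@pytest.fixture(scope="session")
def binning4(scan):
    return phase_bin(extract_respiratory_signal(scan), 4)


@pytest.fixture(scope="session")
def gt_phase_volumes(phantom, breathing, small_grid):
    """Ground-truth phase volumes at the representative motion phase of
    each of 4 bins."""
    vols = [
        rasterize_phantom(phantom, breathing, bin_motion_phase(b, 4),
                          small_grid, supersample=2)
        for b in range(4)
    ]
    return PhaseImageSet(vols)


@pytest.fixture(scope="session")
def normalized_phase_volumes(gt_phase_volumes):
    mx = max(v.data.max() for v in gt_phase_volumes.volumes)
    return PhaseImageSet([
        v.copy_with(v.data / mx, kind="normalized")
        for v in gt_phase_volumes.volumes
    ])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
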