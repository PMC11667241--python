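"""Motion-compensated FDK via warped backprojection trajectories.

Every projection contributes to every target phase: when backprojecting a
projection acquired at phase j into the grid of target phase i, each voxel
p is first displaced to p' = p + D_i^j(p) (the motion model's estimate of
where the tissue at p sits during phase j) before computing its detector
coordinates and distance weight.  With an identity motion model this
reduces exactly to the all-projection FDK reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdk import PhaseImageSet, _backproject, _prepare_filtered
from .geometry import ConeBeamGeometry, GridSpec, Volume, desk_grid
from .projections import ProjectionSet
from .respiratory import PhaseBinning
from .transforms import MotionModel

__all__ = ["MoCoJob", "moco_reconstruct", "moco_reconstruct_4d"]


@dataclass
class MoCoJob:
    """One motion-compensated reconstruction task."""

    projections: ProjectionSet
    binning: PhaseBinning
    geometry: ConeBeamGeometry
    motion_model: MotionModel
    target_phase: int
    grid: GridSpec = None
    window: str = "ram-lak"

    def __post_init__(self):
        if self.grid is None:
            self.grid = desk_grid()
        if self.motion_model.n_phases != self.binning.n_bins:
            raise ValueError("motion model phase count != binning bin count")
        if not (0 <= self.target_phase < self.binning.n_bins):
            raise ValueError("target phase out of range")


def _displaced_coordinates(job: MoCoJob):
    """Per-bin displaced world coordinates for the target phase.

    Returns a function k -> (x, y, z) flattened arrays; caches one
    displaced coordinate set per source bin.
    """
    grid = job.grid
    xx, yy, zz = grid.world_coordinates()
    base = (xx.ravel(), yy.ravel(), zz.ravel())
    sx, sy, sz = grid.spacing
    i = job.target_phase
    cache = {}

    def coords(k):
        j = int(job.binning.labels[k])
        if j not in cache:
            if (i, j) not in job.motion_model:
                raise KeyError(f"motion model lacks displacement D_{i}^{j}")
            d = job.motion_model.field(i, j)
            cache[j] = (
                base[0] + (d[0].ravel() * sx),
                base[1] + (d[1].ravel() * sy),
                base[2] + (d[2].ravel() * sz),
            )
        return cache[j]

    return coords


def moco_reconstruct(job: MoCoJob) -> Volume:
    """Motion-compensated FDK of one target phase using all projections."""
    if not job.geometry.full_fan:
        raise ValueError("half-fan geometry is unsupported")
    filtered = _prepare_filtered(job.projections, job.window)
    coords = _displaced_coordinates(job)
    data = _backproject(filtered, job.geometry, job.grid,
                        job.projections.angles, coords)
    return Volume(data, job.grid, kind="attenuation")


def moco_reconstruct_4d(projections: ProjectionSet, binning: PhaseBinning,
                        geometry: ConeBeamGeometry, motion_model: MotionModel,
                        grid: GridSpec = None,
                        window: str = "ram-lak") -> PhaseImageSet:
    """Motion-compensated FDK for every target phase."""
    vols = []
    for target in range(binning.n_bins):
        job = MoCoJob(projections, binning, geometry, motion_model, target,
                      grid, window)
        vols.append(moco_reconstruct(job))
    return PhaseImageSet(vols)
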