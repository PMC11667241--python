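"""Grids, volumes and circular cone-beam scan geometry.

Conventions used throughout the package
---------------------------------------
* Volume arrays are indexed ``[iz, iy, ix]`` (z slowest, x fastest), matching
  the SimpleITK array convention.
* World coordinates are (x, y, z) in millimetres; z is the superior-inferior
  rotation axis.  By default grids are centred on the isocenter: the world
  origin sits at the grid corner plus half a voxel.
* Gantry angles are in radians, counter-clockwise about +z, with the source
  starting on the +y axis.
* Displacement fields are arrays of shape (3, nz, ny, nx) with channel order
  (dx, dy, dz) in *voxel* units of the fastest-to-slowest grid axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "Volume", "ConeBeamGeometry", "desk_grid", "full_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel grid.

    shape: (nz, ny, nx) voxel counts; spacing: (sx, sy, sz) mm; origin:
    world position (mm) of the centre of voxel (0,0,0).  If origin is None
    the grid is centred on (0,0,0).
    """

    shape: tuple
    spacing: tuple
    origin: tuple = None

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 per axis")
        if self.origin is None:
            nz, ny, nx = self.shape
            sx, sy, sz = self.spacing
            object.__setattr__(
                self,
                "origin",
                (-(nx - 1) * sx / 2.0, -(ny - 1) * sy / 2.0, -(nz - 1) * sz / 2.0),
            )

    @property
    def n_voxels(self):
        return int(np.prod(self.shape))

    def world_coordinates(self):
        """Meshgrid of world (x, y, z) at voxel centres, each (nz,ny,nx)."""
        nz, ny, nx = self.shape
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        x = ox + sx * np.arange(nx)
        y = oy + sy * np.arange(ny)
        z = oz + sz * np.arange(nz)
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        return xx, yy, zz

    def voxel_to_world(self, indices):
        """(..., 3) fractional voxel indices (ix,iy,iz) -> world mm (x,y,z)."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, points):
        """World mm (x,y,z) -> fractional voxel indices (ix,iy,iz)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class Volume:
    """3D scalar field on a :class:`GridSpec`.

    ``kind`` records intensity semantics: attenuation in mm^-1 or a
    normalized [0, 1] range.
    """

    data: np.ndarray
    grid: GridSpec
    kind: str = "attenuation"  # or "normalized"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    def copy_with(self, data, kind=None):
        return Volume(data, self.grid, kind or self.kind)


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular full-fan flat-panel cone-beam geometry.

    sid/sdd: source-isocenter and source-detector distances (mm);
    n_u/n_v: detector columns (lateral) and rows (axial); du/dv: detector
    pixel spacing (mm); angles: per-projection gantry angle (rad).
    """

    sid: float
    sdd: float
    n_u: int
    n_v: int
    du: float
    dv: float
    angles: np.ndarray = field(default=None)
    full_fan: bool = True

    def __post_init__(self):
        if not (self.sdd > self.sid > 0):
            raise ValueError("require SDD > SID > 0")
        if not self.full_fan:
            raise ValueError("half-fan geometry is unsupported")
        if self.angles is not None:
            object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))

    @property
    def n_projections(self):
        return 0 if self.angles is None else len(self.angles)

    def with_angles(self, angles):
        return replace(self, angles=np.asarray(angles, dtype=float))

    def source_position(self, theta):
        """Source world position at gantry angle theta."""
        return self.sid * np.array([-np.sin(theta), np.cos(theta), 0.0])

    def detector_axes(self, theta):
        """(u_hat, v_hat) unit vectors of the detector at angle theta."""
        u_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        return u_hat, v_hat


def evenly_spaced_angles(n, arc=2 * np.pi, start=0.0):
    return start + arc * np.arange(n) / n


def desk_grid():
    """Default reduced-scale reconstruction grid: 64x64x48 at 4 mm."""
    return GridSpec(shape=(48, 64, 64), spacing=(4.0, 4.0, 4.0))


def full_grid():
    """Clinical-scale grid: 224x224x96 voxels at 2 mm spacing."""
    return GridSpec(shape=(96, 224, 224), spacing=(2.0, 2.0, 2.0))


def desk_geometry(n_projections=180):
    """Reduced-scale full-fan geometry with clinical SID/SDD (1000/1500 mm)."""
    return ConeBeamGeometry(
        sid=1000.0,
        sdd=1500.0,
        n_u=96,
        n_v=72,
        du=4.5,
        dv=4.5,
        angles=evenly_spaced_angles(n_projections),
    )
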