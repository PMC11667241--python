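"""Displacement-field algebra: warping, inversion, composition, motion models.

All displacement fields live on a common voxel grid, use the pull
convention (the warped value at voxel p is sampled at p + D(p)) and are
expressed in voxel units with channel order (dx, dy, dz) for the
(fastest ... slowest) array axes — see :mod:`moco4d.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import _gather_trilinear
from .geometry import GridSpec, Volume

__all__ = [
    "DisplacementFieldSet",
    "MotionModel",
    "warp_image",
    "warp_array",
    "sample_field",
    "invert_transform",
    "compose_transforms",
    "build_motion_model",
]


def _coordinate_grids(shape, dtype=float):
    nz, ny, nx = shape
    return np.meshgrid(
        np.arange(nz, dtype=dtype),
        np.arange(ny, dtype=dtype),
        np.arange(nx, dtype=dtype),
        indexing="ij",
    )


def warp_array(img: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Trilinear pull-warp of a 3D array by a (3,Z,Y,X) voxel displacement."""
    img = np.asarray(img)
    disp = np.asarray(disp)
    if disp.shape != (3,) + img.shape:
        raise ValueError(f"displacement shape {disp.shape} does not match image "
                         f"{img.shape}")
    gz, gy, gx = _coordinate_grids(img.shape)
    val, *_ = _gather_trilinear(img, gz + disp[2], gy + disp[1], gx + disp[0])
    return val


def warp_image(image: Volume, disp: np.ndarray) -> Volume:
    """Warp a :class:`Volume` by a displacement field on its own grid."""
    return image.copy_with(warp_array(image.data, disp))


def sample_field(field: np.ndarray, zc, yc, xc) -> np.ndarray:
    """Trilinear sample of each component of a (3,Z,Y,X) field."""
    return np.stack(
        [_gather_trilinear(field[c], zc, yc, xc)[0] for c in range(3)], axis=0
    )


def invert_transform(disp: np.ndarray, tol: float = 0.01,
                     max_iter: int = 50) -> np.ndarray:
    """Fixed-point inverse of a displacement field.

    Iterates D_inv(p) <- -D(p + D_inv(p)) from zero until the maximum
    update falls below ``tol`` voxels.  Raises if the update fails to
    contract for five consecutive iterations (divergence or bounded
    oscillation, e.g. a non-invertible field).
    """
    disp = np.asarray(disp)
    gz, gy, gx = _coordinate_grids(disp.shape[1:], dtype=disp.dtype)
    inv = np.zeros_like(disp)
    prev_update = np.inf
    growth = 0
    for _ in range(max_iter):
        sampled = sample_field(disp, gz + inv[2], gy + inv[1], gx + inv[0])
        new = -sampled
        update = np.max(np.abs(new - inv))
        inv = new
        if update < tol:
            break
        if update >= prev_update and update > 0.5:
            # slow sub-voxel plateaus are tolerated (return best effort);
            # large non-contracting updates mean a non-invertible field
            growth += 1
            if growth >= 5:
                raise RuntimeError(
                    f"displacement inversion diverging (update {update:.3g} voxels)"
                )
        else:
            growth = 0
        prev_update = update
    return inv


def compose_transforms(disp_a: np.ndarray, disp_b: np.ndarray) -> np.ndarray:
    """Displacement field of the composition T_a o T_b.

    D_c(p) = D_b(p) + D_a(p + D_b(p)), with trilinear sampling of D_a.
    """
    disp_a = np.asarray(disp_a)
    disp_b = np.asarray(disp_b)
    if disp_a.shape != disp_b.shape:
        raise ValueError("displacement shapes differ")
    gz, gy, gx = _coordinate_grids(disp_a.shape[1:], dtype=disp_a.dtype)
    sampled = sample_field(disp_a, gz + disp_b[2], gy + disp_b[1], gx + disp_b[0])
    return disp_b + sampled


@dataclass
class DisplacementFieldSet:
    """Per-phase displacements to the implicit template: D_tem^n.

    fields: (N, 3, nz, ny, nx) voxel-unit displacements; T_tem^n(p) =
    p + D_tem^n(p) samples phase n at template voxel p.
    """

    fields: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.fields = np.asarray(self.fields)
        n = self.fields.shape[0]
        if self.fields.shape != (n, 3) + tuple(self.grid.shape):
            raise ValueError("fields must have shape (N, 3, nz, ny, nx)")
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("displacement fields must be finite")

    @property
    def n_phases(self):
        return self.fields.shape[0]


class MotionModel:
    """All pairwise inter-phase transformations T_i^j.

    D_i^j pulls phase j onto the phase-i grid (I_i = I_j o T_i^j); the
    diagonal is identically zero.
    """

    def __init__(self, pair_fields: dict, n_phases: int, grid: GridSpec,
                 is_identity: bool = False):
        self.n_phases = n_phases
        self.grid = grid
        self._fields = pair_fields
        self.is_identity = is_identity

    def field(self, i: int, j: int) -> np.ndarray:
        """Displacement D_i^j (zero when i == j or for the identity model)."""
        if not (0 <= i < self.n_phases and 0 <= j < self.n_phases):
            raise KeyError(f"phase pair ({i}, {j}) out of range")
        if i == j or self.is_identity:
            return np.zeros((3,) + tuple(self.grid.shape))
        if (i, j) not in self._fields:
            raise KeyError(f"motion model lacks displacement D_{i}^{j}")
        return self._fields[(i, j)]

    @staticmethod
    def identity(n_phases: int, grid: GridSpec) -> "MotionModel":
        """Model whose every pairwise displacement is zero."""
        return MotionModel({}, n_phases, grid, is_identity=True)

    def __contains__(self, pair):
        i, j = pair
        return i == j or self.is_identity or (i, j) in self._fields


def build_motion_model(dvfs: DisplacementFieldSet) -> MotionModel:
    """Inter-phase motion model from template displacements.

    For each ordered pair (i, j): D_i^j realizes T_i^j = T_tem^j o
    (T_tem^i)^-1, i.e. compose(D_tem^j, invert(D_tem^i)).
    """
    n = dvfs.n_phases
    inverses = [invert_transform(dvfs.fields[i]) for i in range(n)]
    pairs = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pairs[(i, j)] = compose_transforms(dvfs.fields[j], inverses[i])
    return MotionModel(pairs, n, dvfs.grid)
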