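"""Cone-beam projection stacks and the exact ray-driven forward projector."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numba

from .geometry import ConeBeamGeometry, Volume

__all__ = ["ProjectionSet", "forward_project"]


@dataclass
class ProjectionSet:
    """Stack of 2D line-integral projections with angles and timestamps.

    data: (n_projections, n_v, n_u) array of unitless line integrals.
    """

    data: np.ndarray
    angles: np.ndarray
    timestamps: np.ndarray
    geometry: ConeBeamGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n, nv, nu = self.data.shape
        if nv != self.geometry.n_v or nu != self.geometry.n_u:
            raise ValueError("projection shape inconsistent with geometry")
        if len(self.angles) != n or len(self.timestamps) != n:
            raise ValueError("angles/timestamps length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("projection values must be finite")

    @property
    def n_projections(self):
        return self.data.shape[0]

    def subset(self, indices):
        idx = np.asarray(indices)
        return ProjectionSet(
            self.data[idx], self.angles[idx], self.timestamps[idx], self.geometry
        )


@numba.njit(cache=True)
def _siddon_project(vol, xmin, ymin, zmin, sx, sy, sz,
                    src, pix_x, pix_y, pix_z, out):
    """Exact ray/voxel traversal line integrals (Siddon).

    vol indexed [iz, iy, ix]; grid box corner (xmin, ymin, zmin); pixel
    world positions flattened; writes line integrals into out (flat).
    """
    nz, ny, nx = vol.shape
    xmax = xmin + nx * sx
    ymax = ymin + ny * sy
    zmax = zmin + nz * sz
    eps = 1e-12
    for r in range(pix_x.size):
        dx = pix_x[r] - src[0]
        dy = pix_y[r] - src[1]
        dz = pix_z[r] - src[2]
        amin = 0.0
        amax = 1.0
        # slab clipping
        if abs(dx) > eps:
            a1 = (xmin - src[0]) / dx
            a2 = (xmax - src[0]) / dx
            if a1 > a2:
                a1, a2 = a2, a1
            amin = max(amin, a1)
            amax = min(amax, a2)
        elif src[0] < xmin or src[0] > xmax:
            out[r] = 0.0
            continue
        if abs(dy) > eps:
            a1 = (ymin - src[1]) / dy
            a2 = (ymax - src[1]) / dy
            if a1 > a2:
                a1, a2 = a2, a1
            amin = max(amin, a1)
            amax = min(amax, a2)
        elif src[1] < ymin or src[1] > ymax:
            out[r] = 0.0
            continue
        if abs(dz) > eps:
            a1 = (zmin - src[2]) / dz
            a2 = (zmax - src[2]) / dz
            if a1 > a2:
                a1, a2 = a2, a1
            amin = max(amin, a1)
            amax = min(amax, a2)
        elif src[2] < zmin or src[2] > zmax:
            out[r] = 0.0
            continue
        if amin >= amax:
            out[r] = 0.0
            continue
        ray_len = (dx * dx + dy * dy + dz * dz) ** 0.5
        # entry voxel
        a = amin + eps
        px = src[0] + a * dx
        py = src[1] + a * dy
        pz = src[2] + a * dz
        ix = int((px - xmin) / sx)
        iy = int((py - ymin) / sy)
        iz = int((pz - zmin) / sz)
        if ix < 0:
            ix = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy > ny - 1:
            iy = ny - 1
        if iz < 0:
            iz = 0
        if iz > nz - 1:
            iz = nz - 1
        # parametric step sizes and next-crossing parameters
        big = 1e30
        if abs(dx) > eps:
            da_x = sx / abs(dx)
            step_x = 1 if dx > 0 else -1
            nxt = xmin + (ix + (1 if dx > 0 else 0)) * sx
            ax = (nxt - src[0]) / dx
        else:
            da_x = big
            step_x = 0
            ax = big
        if abs(dy) > eps:
            da_y = sy / abs(dy)
            step_y = 1 if dy > 0 else -1
            nxt = ymin + (iy + (1 if dy > 0 else 0)) * sy
            ay = (nxt - src[1]) / dy
        else:
            da_y = big
            step_y = 0
            ay = big
        if abs(dz) > eps:
            da_z = sz / abs(dz)
            step_z = 1 if dz > 0 else -1
            nxt = zmin + (iz + (1 if dz > 0 else 0)) * sz
            az = (nxt - src[2]) / dz
        else:
            da_z = big
            step_z = 0
            az = big
        acc = 0.0
        a_cur = amin
        while a_cur < amax - eps:
            if ax <= ay and ax <= az:
                a_next = ax
            elif ay <= az:
                a_next = ay
            else:
                a_next = az
            if a_next > amax:
                a_next = amax
            seg = (a_next - a_cur) * ray_len
            if seg > 0.0:
                acc += seg * vol[iz, iy, ix]
            a_cur = a_next
            if ax <= ay and ax <= az:
                ix += step_x
                ax += da_x
            elif ay <= az:
                iy += step_y
                ay += da_y
            else:
                iz += step_z
                az += da_z
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                break
        out[r] = acc


def forward_project(volume: Volume, geometry: ConeBeamGeometry,
                    angles=None) -> np.ndarray:
    """Line integrals of an attenuation volume for each gantry angle.

    Returns an array (n_angles, n_v, n_u) of unitless integrals (mm^-1 * mm).
    """
    if angles is None:
        angles = geometry.angles
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    grid = volume.grid
    sx, sy, sz = grid.spacing
    ox, oy, oz = grid.origin
    xmin, ymin, zmin = ox - sx / 2, oy - sy / 2, oz - sz / 2
    vol = np.ascontiguousarray(volume.data, dtype=np.float64)
    n_u, n_v = geometry.n_u, geometry.n_v
    u = (np.arange(n_u) - (n_u - 1) / 2.0) * geometry.du
    v = (np.arange(n_v) - (n_v - 1) / 2.0) * geometry.dv
    vv, uu = np.meshgrid(v, u, indexing="ij")
    out = np.empty((len(angles), n_v, n_u), dtype=np.float64)
    for k, theta in enumerate(angles):
        src = geometry.source_position(theta)
        u_hat, v_hat = geometry.detector_axes(theta)
        det_center = -(geometry.sdd - geometry.sid) * np.array(
            [-np.sin(theta), np.cos(theta), 0.0]
        )
        pix = (det_center[None, :]
               + uu.ravel()[:, None] * u_hat[None, :]
               + vv.ravel()[:, None] * v_hat[None, :])
        flat = np.empty(pix.shape[0], dtype=np.float64)
        _siddon_project(vol, xmin, ymin, zmin, sx, sy, sz,
                        src.astype(np.float64),
                        np.ascontiguousarray(pix[:, 0]),
                        np.ascontiguousarray(pix[:, 1]),
                        np.ascontiguousarray(pix[:, 2]),
                        flat)
        out[k] = flat.reshape(n_v, n_u)
    return out
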