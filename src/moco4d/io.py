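"""Readers and writers for volumes, projections, displacement fields, models.

Volumes go through SimpleITK (MHA or NIfTI chosen by extension), preserving
spacing and origin.  Projection stacks are stored as 3D MHA plus a JSON
geometry sidecar; displacement-field sets as 4D MHA (component-major) plus
a JSON manifest recording the voxel-unit, pull-convention, (dx, dy, dz)
channel layout.  Network parameters serialize to a single ``.npz`` with a
JSON header entry.
"""

from __future__ import annotations

import json


import numpy as np
import SimpleITK as sitk

from .geometry import ConeBeamGeometry, GridSpec, Volume
from .projections import ProjectionSet
from .transforms import DisplacementFieldSet

__all__ = [
    "write_volume",
    "read_volume",
    "write_projections",
    "read_projections",
    "write_dvf_set",
    "read_dvf_set",
    "save_model",
    "load_model_state",
]


def _volume_to_sitk(volume: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(volume.data, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in volume.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.grid.origin))
    return img


def write_volume(path, volume: Volume):
    """Write a Volume as MHA or NIfTI (by extension)."""
    sitk.WriteImage(_volume_to_sitk(volume), str(path))


def read_volume(path, kind="attenuation") -> Volume:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)
    grid = GridSpec(shape=data.shape, spacing=tuple(img.GetSpacing()),
                    origin=tuple(img.GetOrigin()))
    return Volume(data, grid, kind=kind)


def write_projections(path, projections: ProjectionSet):
    """MHA stack plus JSON geometry sidecar at <path>.json."""
    img = sitk.GetImageFromArray(np.asarray(projections.data, dtype=np.float64))
    sitk.WriteImage(img, str(path))
    geo = projections.geometry
    sidecar = {
        "sid_mm": geo.sid,
        "sdd_mm": geo.sdd,
        "n_u": geo.n_u,
        "n_v": geo.n_v,
        "du_mm": geo.du,
        "dv_mm": geo.dv,
        "full_fan": geo.full_fan,
        "angles_rad": list(map(float, projections.angles)),
        "timestamps_s": list(map(float, projections.timestamps)),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_projections(path) -> ProjectionSet:
    data = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    with open(str(path) + ".json") as fh:
        sc = json.load(fh)
    geometry = ConeBeamGeometry(
        sid=sc["sid_mm"], sdd=sc["sdd_mm"], n_u=sc["n_u"], n_v=sc["n_v"],
        du=sc["du_mm"], dv=sc["dv_mm"], angles=np.asarray(sc["angles_rad"]),
        full_fan=sc.get("full_fan", True),
    )
    return ProjectionSet(data, np.asarray(sc["angles_rad"]),
                         np.asarray(sc["timestamps_s"]), geometry)


def write_dvf_set(path, dvfs: DisplacementFieldSet):
    """(N,3,Z,Y,X) fields as one 4D MHA plus a JSON manifest."""
    n = dvfs.n_phases
    arr = np.asarray(dvfs.fields, dtype=np.float64).reshape(
        (n * 3,) + tuple(dvfs.grid.shape)
    )
    img = sitk.GetImageFromArray(arr.reshape(n * 3 * dvfs.grid.shape[0],
                                             *dvfs.grid.shape[1:]))
    sitk.WriteImage(img, str(path))
    manifest = {
        "n_phases": n,
        "shape_zyx": list(dvfs.grid.shape),
        "spacing_mm": list(dvfs.grid.spacing),
        "origin_mm": list(dvfs.grid.origin),
        "units": "voxels",
        "convention": "pull: warped(p) = image(p + D(p))",
        "channel_order": "dx, dy, dz (fastest-to-slowest grid axis)",
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(manifest, fh)


def read_dvf_set(path) -> DisplacementFieldSet:
    with open(str(path) + ".json") as fh:
        mf = json.load(fh)
    data = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    shape = tuple(mf["shape_zyx"])
    n = mf["n_phases"]
    fields = data.reshape((n, 3) + shape)
    grid = GridSpec(shape=shape, spacing=tuple(mf["spacing_mm"]),
                    origin=tuple(mf["origin_mm"]))
    return DisplacementFieldSet(fields, grid)


def save_model(path, module, header: dict):
    """Network parameters + JSON header in one .npz file."""
    state = {f"param/{k}": v for k, v in module.state_dict().items()}
    state["header"] = np.frombuffer(
        json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(str(path), **state)


def load_model_state(path):
    """Returns (state dict, header dict)."""
    with np.load(str(path)) as npz:
        header = json.loads(bytes(npz["header"]).decode())
        state = {
            k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")
        }
    return state, header
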