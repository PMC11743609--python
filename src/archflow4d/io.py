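"""Readers and writers for the package's on-disk formats.

Masks travel as NIfTI (spacing in the header), velocity fields as one
4D NIfTI per component plus a JSON sidecar declaring units (cm/s),
frame duration, venc and heart rate, centerlines as legacy ASCII VTK
polylines with a JSON sidecar holding the tree structure, meshes as
binary STL, and cohort tables as CSV with a column-dictionary JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Bifurcation, CenterlineTree, VelocityField4D, VoxelMask

__all__ = [
    "save_mask", "load_mask", "save_velocity_field", "load_velocity_field",
    "save_centerline", "load_centerline", "save_mesh_stl",
    "save_cohort", "load_cohort",
]


class FormatError(ValueError):
    """Inconsistent or incomplete on-disk data."""


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_mask(mask: VoxelMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))


def load_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    aff = img.affine
    return VoxelMask(np.asanyarray(img.dataobj) > 0,
                     np.abs(np.diag(aff)[:3]), aff[:3, 3])


def save_velocity_field(field: VelocityField4D, directory,
                        prefix: str = "vel") -> None:
    """One 4D NIfTI per component (+ mask) and a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.spacing, field.lumen_mask.origin)
    for name, arr in (("u", field.u), ("v", field.v), ("w", field.w)):
        data = np.moveaxis(arr, 0, -1)  # (x, y, z, t)
        nib.save(nib.Nifti1Image(data, aff),
                 str(directory / f"{prefix}_{name}.nii.gz"))
    save_mask(field.lumen_mask, directory / f"{prefix}_mask.nii.gz")
    sidecar = {
        "units": "cm/s",
        "frame_duration_ms": field.frame_duration,
        "n_frames": field.n_frames,
        "venc": field.meta.get("venc"),
        "heart_rate": field.meta.get("heart_rate"),
        "flux_curve_ml_per_s": (None if field.flux_curve is None
                                else list(map(float, field.flux_curve))),
        "meta": {k: v for k, v in field.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_velocity_field(directory, prefix: str = "vel") -> VelocityField4D:
    directory = Path(directory)
    sidecar_path = directory / f"{prefix}.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("units") != "cm/s":
        raise FormatError("sidecar must declare velocities in cm/s")
    if "frame_duration_ms" not in sidecar:
        raise FormatError("sidecar must declare frame_duration_ms")
    comps = []
    spacing = None
    for name in ("u", "v", "w"):
        img = nib.load(str(directory / f"{prefix}_{name}.nii.gz"))
        arr = np.moveaxis(np.asanyarray(img.dataobj), -1, 0)
        comps.append(arr.astype(np.float32))
        sp = np.abs(np.diag(img.affine)[:3])
        if spacing is None:
            spacing = sp
        elif not np.allclose(sp, spacing):
            raise FormatError("component volumes have mismatched spacing")
    if len({c.shape for c in comps}) != 1:
        raise FormatError("component volumes have mismatched shapes")
    mask = load_mask(directory / f"{prefix}_mask.nii.gz")
    flux = sidecar.get("flux_curve_ml_per_s")
    meta = dict(sidecar.get("meta", {}))
    meta.setdefault("venc", sidecar.get("venc"))
    meta.setdefault("heart_rate", sidecar.get("heart_rate"))
    return VelocityField4D(comps[0], comps[1], comps[2], spacing,
                           float(sidecar["frame_duration_ms"]), mask,
                           None if flux is None else np.asarray(flux),
                           meta)


# --------------------------------------------------------------------------
# Centerline (legacy ASCII VTK polydata + JSON sidecar)
# --------------------------------------------------------------------------

def save_centerline(tree: CenterlineTree, path) -> None:
    """Legacy ASCII VTK polylines (main path + branches) + JSON sidecar.

    The VTK file carries the geometry for viewers; the sidecar carries
    everything needed to reconstruct the tree bit-exactly.
    """
    path = Path(path)
    blocks = [tree.points] + [b.branch_points for b in tree.bifurcations]
    total = sum(len(b) for b in blocks)
    lines = ["# vtk DataFile Version 3.0", "arch centerline", "ASCII",
             "DATASET POLYDATA", f"POINTS {total} float"]
    for block in blocks:
        for p in block:
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    sizes = [len(b) for b in blocks]
    lines.append(f"LINES {len(blocks)} {sum(s + 1 for s in sizes)}")
    start = 0
    for s in sizes:
        lines.append(" ".join(map(str, [s] + list(range(start, start + s)))))
        start += s
    scalars = np.concatenate(
        [tree.radius] + [np.zeros(len(b.branch_points))
                         for b in tree.bifurcations])
    lines.append(f"POINT_DATA {total}")
    lines.append("SCALARS radius float 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.6f}" for v in scalars)
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "points": tree.points.tolist(),
        "arc": tree.arc.tolist(),
        "radius": np.asarray(tree.radius).tolist(),
        "tangent_window": tree.tangent_window,
        "bovine": tree.bovine,
        "bifurcations": [
            {"arc_position": b.arc_position, "point": b.point.tolist(),
             "branch_points": b.branch_points.tolist(),
             "branch_arc": b.branch_arc.tolist(), "name": b.name}
            for b in tree.bifurcations],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar))


def load_centerline(path) -> CenterlineTree:
    path = Path(path)
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    bifs = [Bifurcation(b["arc_position"], np.array(b["point"]),
                        np.array(b["branch_points"]),
                        np.array(b["branch_arc"]), b["name"])
            for b in sidecar["bifurcations"]]
    return CenterlineTree(np.array(sidecar["points"]),
                          np.array(sidecar["arc"]),
                          np.array(sidecar["radius"]), bifs,
                          tangent_window=sidecar["tangent_window"],
                          bovine=sidecar["bovine"])


def save_mesh_stl(mesh, path) -> None:
    mesh.export(str(path))


def save_cohort(cohort: pd.DataFrame, path,
                column_dictionary: Optional[dict] = None) -> None:
    path = Path(path)
    cohort.to_csv(path, index=False)
    if column_dictionary is not None:
        path.with_suffix(".columns.json").write_text(
            json.dumps(column_dictionary, indent=2))


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
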