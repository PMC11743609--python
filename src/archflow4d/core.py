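"""Shared in-memory containers for masks, velocity fields and centerlines.

Conventions used throughout the package:

* world coordinates are millimetres, axis order ``(x=left-right,
  y=anterior-posterior, z=inferior-superior)``;
* voxel indices are 0-based and voxel centres sit at
  ``origin + index * spacing``;
* velocities are cm/s, angles are degrees.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class PhantomError(ValueError):
    """Invalid phantom / analysis parameters."""


class ResolutionError(PhantomError):
    """Requested voxel spacing cannot resolve the smallest structure."""


class TopologyError(ValueError):
    """Lumen mask does not have the expected tubular topology."""


@dataclass
class VoxelMask:
    """Binary lumen volume on a regular grid.

    Attributes
    ----------
    data:
        3D boolean array, axes (x, y, z).
    spacing:
        mm per axis, length 3, all positive.
    origin:
        world position (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise PhantomError("mask data must be 3D")
        if np.any(self.spacing <= 0):
            raise PhantomError("spacing must be positive on all axes")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Lumen volume in mm^3."""
        return float(self.data.sum()) * self.voxel_volume

    def voxel_centers(self, where: Optional[np.ndarray] = None) -> np.ndarray:
        """World coordinates (mm) of voxel centres.

        Parameters
        ----------
        where:
            optional boolean array selecting voxels; defaults to the lumen.
        """
        sel = self.data if where is None else where
        idx = np.argwhere(sel)
        return self.origin[None, :] + idx * self.spacing[None, :]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.origin[None, :]) / self.spacing[None, :]

    def copy(self) -> "VoxelMask":
        return VoxelMask(self.data.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity volume (cm/s).

    ``u, v, w`` are the x/y/z velocity components, each of shape
    ``(n_frames, nx, ny, nz)`` on the grid of ``lumen_mask``.  Velocities
    are zero outside the lumen.  ``flux_curve`` (ml/s per frame), when
    present, is the prescribed or measured inlet volume flux used for the
    systole/diastole split.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    spacing: np.ndarray
    frame_duration: float  # ms
    lumen_mask: VoxelMask
    flux_curve: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        shapes = {self.u.shape, self.v.shape, self.w.shape}
        if len(shapes) != 1:
            raise PhantomError("velocity components must share one grid")
        if self.u.ndim != 4:
            raise PhantomError("velocity components must be (t, x, y, z)")
        if self.u.shape[1:] != self.lumen_mask.data.shape:
            raise PhantomError("velocity grid does not match lumen mask")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    def frame(self, t: int) -> np.ndarray:
        """Stacked (3, nx, ny, nz) velocity vector field of frame ``t``."""
        return np.stack([self.u[t], self.v[t], self.w[t]])

    def speed(self, t: int) -> np.ndarray:
        return np.sqrt(self.u[t] ** 2 + self.v[t] ** 2 + self.w[t] ** 2)

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            self.u.copy(), self.v.copy(), self.w.copy(), self.spacing.copy(),
            self.frame_duration, self.lumen_mask.copy(),
            None if self.flux_curve is None else np.array(self.flux_curve),
            dict(self.meta),
        )


@dataclass
class Bifurcation:
    """A branch take-off on the main arch path."""

    arc_position: float          # mm along the main path
    point: np.ndarray            # world mm
    branch_points: np.ndarray    # (m, 3) ordered away from the take-off
    branch_arc: np.ndarray       # (m,) arc length along the branch, mm
    name: str = ""


@dataclass
class CenterlineTree:
    """Ordered arch centerline with branch take-offs.

    ``points`` run inlet (ascending aorta) to outlet (descending aorta);
    ``arc`` is the cumulative arc length (mm, strictly increasing) and
    ``radius`` the local distance to the lumen boundary (mm).
    Bifurcations are ordered by arc position: b1 = brachiocephalic
    (innominate), b2 = left common carotid, b3 = left subclavian; for a
    bovine arch b1 = common trunk and b2 = left subclavian.
    """

    points: np.ndarray
    arc: np.ndarray
    radius: np.ndarray
    bifurcations: list
    tangent_window: float = 4.0
    bovine: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc) <= 0):
            raise TopologyError("arc length must be strictly increasing")
        arcs = [b.arc_position for b in self.bifurcations]
        if np.any(np.diff(arcs) <= 0):
            raise TopologyError("bifurcation arc positions must be increasing")

    @property
    def total_length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Interpolated main-path point at arc length ``s``."""
        s = float(np.clip(s, self.arc[0], self.arc[-1]))
        return np.array([np.interp(s, self.arc, self.points[:, k]) for k in range(3)])

    def radius_at(self, s: float) -> float:
        return float(np.interp(s, self.arc, self.radius))

    def n_branches(self) -> int:
        return len(self.bifurcations)


def rotation_matrix(axis: str, angle_deg: float) -> np.ndarray:
    """Right-handed rotation about one of the world axes ('x'|'y'|'z')."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
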