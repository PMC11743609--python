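"""Synthetic neonatal aortic-arch phantoms.

This module builds everything the downstream analyses need without any
patient data: analytic arch centerlines for the three post-repair arch
morphologies (roman, crenel, gothic), voxelized lumen masks emulating
black-blood-derived segmentations, pulsatile three-component velocity
fields with controlled axial / helical / vortical content, and synthetic
patient cohorts for the statistics layer.

The arch is laid out in a (tiltable) sagittal plane: the ascending aorta
is the anterior limb (+y), the descending aorta the posterior limb, and
the three supra-aortic branches leave the transverse segment superiorly.
All generator geometry is analytic, so bifurcation angles, branch spans
and lumen radii are known exactly and serve as ground truth for the
recovery tests of the geometry module.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .core import (PhantomError, ResolutionError, VelocityField4D, VoxelMask,
                   Bifurcation, CenterlineTree)

__all__ = [
    "ArchSpec", "FlowSpec", "CohortSpec", "AnalyticCenterline",
    "build_arch_centerline", "voxelize_arch", "synthesize_flow",
    "resample_field", "generate_cohort", "waveform",
]


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

#: lumen radii (mm) at the named arch levels; neonatal post-repair scale.
DEFAULT_LUMEN_RADII = {
    "aao": 4.0, "prox_arch": 3.6, "distal_arch": 3.3,
    "isthmus": 3.0, "dao": 3.2,
}


@dataclass
class ArchSpec:
    """Parameters of one analytic arch phantom.

    ``arch_width`` is the horizontal (AP) distance between the ascending
    and descending limb axes, ``arch_height`` the apex elevation above the
    limb reference level, and ``transverse_length`` the length of the
    horizontal top segment (zero for a round arch).  Branch take-off
    angles are measured between the branch direction and the local
    downstream arch tangent.  ``branch_arc_positions`` are arc lengths
    (mm) from the inlet.  If ``bovine``, only two branches are generated
    (common trunk + left subclavian) using the first two entries.
    """

    shape_label: str
    arch_width: float
    arch_height: float
    transverse_length: float
    branch_arc_positions: tuple
    branch_angles: tuple = (90.0, 90.0, 90.0)
    branch_azimuths: tuple = (-30.0, 0.0, 30.0)  # out-of-plane fan, degrees
    branch_radii: tuple = (1.8, 1.6, 1.7)
    lumen_radii: dict = field(default_factory=lambda: dict(DEFAULT_LUMEN_RADII))
    bovine: bool = False
    seed: int = 0
    ap_tilt_deg: float = 0.0
    aao_extension: float = 8.0
    dao_extension: float = 30.0
    branch_length: float = 15.0
    apex_round_radius: float = 2.0
    isthmus_offset: float = 8.0     # arc distance of the isthmus dip past b3
    isthmus_sigma: float = 3.0      # axial width (mm) of the isthmus dip
    rotation: Optional[np.ndarray] = None  # extra rigid rotation (3x3)

    def __post_init__(self) -> None:
        if self.shape_label not in ("roman", "crenel", "gothic"):
            raise PhantomError(f"unknown shape {self.shape_label!r}")
        pos = np.asarray(self.branch_arc_positions, dtype=float)
        n_expected = 2 if self.bovine else 3
        if len(pos) < n_expected:
            raise PhantomError("too few branch arc positions")
        if np.any(np.diff(pos[:n_expected]) <= 0):
            raise PhantomError("branch arc positions must be strictly increasing")
        if any(r <= 0 for r in self.branch_radii) or \
                any(r <= 0 for r in self.lumen_radii.values()):
            raise PhantomError("all radii must be positive")
        if self.transverse_length < 0:
            raise PhantomError("transverse_length must be >= 0")

    @property
    def n_branches(self) -> int:
        return 2 if self.bovine else 3

    @staticmethod
    def canonical(shape: str, branch_span: Optional[float] = None,
                  branch_angles: Optional[Sequence[float]] = None,
                  arch_angle: Optional[float] = None,
                  **overrides) -> "ArchSpec":
        """Reference phantom for one of the three arch morphologies.

        The arch width is solved numerically so that the apex-vertex
        arch angle of the continuous model equals ``arch_angle`` (default:
        the group value typical for each post-repair shape class —
        gothic 97 deg, roman 109 deg, crenel 117 deg), and branch arc
        positions are solved so the straight-line first-to-last take-off
        distance equals ``branch_span`` (defaults 3.4 / 7.1 / 11.9 mm).
        Passing ``arch_width`` explicitly skips the angle calibration.
        """
        from scipy.optimize import brentq

        targets = {"roman": (109.0, 7.1), "crenel": (117.0, 11.9),
                   "gothic": (97.0, 3.4)}
        if shape not in targets:
            raise PhantomError(f"unknown shape {shape!r}")
        angle_t, span_t = targets[shape]
        if arch_angle is not None:
            angle_t = arch_angle
        span = span_t if branch_span is None else branch_span
        if shape == "roman":
            base = dict(shape_label="roman", arch_height=8.0,
                        transverse_length=0.0, apex_round_radius=6.0)
            shift, bracket = 0.0, (12.0, 36.0)
        elif shape == "gothic":
            # the limbs grow with the branch span so the cluster fits on
            # the ascending limb, fully proximal to the point of the arch:
            # the head vessels arise before the apex, and a take-off
            # distal to the point would collide with the ascending limb
            base = dict(shape_label="gothic",
                        arch_height=max(9.0, 0.9 * span + 2.0),
                        transverse_length=0.0, apex_round_radius=4.0)
            shift, bracket = -(span / 2 + 5.0), (max(10.0, span + 4.0), 44.0)
        else:
            # the transverse segment grows with the requested span so the
            # branch cluster stays on the flat top
            base = dict(shape_label="crenel", arch_height=6.0,
                        transverse_length=max(14.0, span + 6.0),
                        apex_round_radius=3.0)
            shift, bracket = -2.0, (max(14.0, span + 6.0) + 7.0, 52.0)
        base.update(overrides)
        if branch_angles is not None:
            base["branch_angles"] = tuple(branch_angles)

        def build(width: float) -> ArchSpec:
            spec = ArchSpec(arch_width=width,
                            branch_arc_positions=(1.0, 2.0, 3.0), **base)
            return replace(spec, branch_arc_positions=_solve_branch_positions(
                spec, span, shift))

        if "arch_width" in base:
            width = base.pop("arch_width")
            return build(width)
        width = brentq(
            lambda w: AnalyticCenterline(build(w)).arch_angle_analytic()
            - angle_t, *bracket, xtol=1e-4)
        return build(width)


@dataclass
class FlowSpec:
    """Parameters of one synthetic pulsatile velocity field.

    ``helix_ratio`` sets the tangential-to-axial speed ratio of the
    corkscrew component; positive means right-handed rotation about the
    downstream flow direction (right-hand rule).  ``vortex``, if given,
    is a dict with keys ``arc_center`` (mm), ``strength`` (cm/s at the
    core edge) and ``core_radius`` (mm) adding an in-plane solid-body
    rotation patch centred on the main path.
    """

    heart_rate: float = 120.0     # beats/min (pump rate of the flow phantom)
    n_frames: int = 20            # frames per cycle
    peak_flux: float = 20.0       # ml/s at the inlet
    time_to_peak: float = 0.4     # fraction of systole
    systolic_fraction: float = 0.4  # fraction of the cycle
    helix_ratio: float = 0.0
    vortex: Optional[dict] = None
    noise_sd: float = 0.0         # cm/s
    venc: float = 150.0           # cm/s
    clip_to_venc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 4:
            raise PhantomError("n_frames must be >= 4")
        if self.venc <= 0:
            raise PhantomError("venc must be positive")
        if abs(self.helix_ratio) > 2:
            raise PhantomError("|helix_ratio| must be <= 2")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if not (0 < self.systolic_fraction < 1 and 0 < self.time_to_peak < 1):
            raise PhantomError("waveform fractions must be in (0,1)")

    @property
    def cycle_duration(self) -> float:
        """Cycle length in ms."""
        return 60000.0 / self.heart_rate

    @property
    def frame_duration(self) -> float:
        return self.cycle_duration / self.n_frames


def waveform(tfrac: np.ndarray, time_to_peak: float = 0.4,
             systolic_fraction: float = 0.4) -> np.ndarray:
    """Smooth raised-cosine systolic pulse, quiescent diastole.

    ``tfrac`` is the cycle fraction in [0, 1).  The pulse rises over
    ``time_to_peak * systolic_fraction`` of the cycle, peaks at 1, falls
    back to zero at the end of systole, and is zero in diastole.  The
    cycle integral is ``systolic_fraction / 2`` exactly.
    """
    t = np.mod(np.asarray(tfrac, dtype=float), 1.0)
    fs, tp = systolic_fraction, time_to_peak
    rise_end = fs * tp
    out = np.zeros_like(t)
    rising = t < rise_end
    out[rising] = 0.5 * (1 - np.cos(np.pi * t[rising] / rise_end))
    falling = (t >= rise_end) & (t < fs)
    out[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - rise_end) / (fs - rise_end)))
    return out


# --------------------------------------------------------------------------
# Planar path segments
# --------------------------------------------------------------------------

class _Line:
    def __init__(self, p0, p1):
        self.p0 = np.asarray(p0, float)
        d = np.asarray(p1, float) - self.p0
        self.length = float(np.hypot(*d))
        self.dir = d / self.length

    def point(self, s):
        s = np.asarray(s, float)
        return self.p0[None, :] + s[..., None] * self.dir[None, :]

    def tangent(self, s):
        s = np.asarray(s, float)
        return np.broadcast_to(self.dir, s.shape + (2,)).copy()


class _Arc:
    """Circular arc from angle a0 to a1 (radians, CCW positive)."""

    def __init__(self, center, radius, a0, a1):
        self.center = np.asarray(center, float)
        self.radius = float(radius)
        self.a0, self.a1 = float(a0), float(a1)
        self.length = abs(a1 - a0) * self.radius
        self.sign = 1.0 if a1 > a0 else -1.0

    def _angle(self, s):
        return self.a0 + self.sign * np.asarray(s, float) / self.radius

    def point(self, s):
        a = self._angle(s)
        return self.center[None, :] + self.radius * np.stack(
            [np.cos(a), np.sin(a)], axis=-1)

    def tangent(self, s):
        a = self._angle(s)
        return self.sign * np.stack([-np.sin(a), np.cos(a)], axis=-1)


class _PlanarPath:
    def __init__(self, segments):
        self.segments = segments
        self.cum = np.concatenate([[0.0], np.cumsum([seg.length for seg in segments])])
        self.total_length = float(self.cum[-1])

    def _locate(self, s):
        s = np.clip(np.asarray(s, float), 0.0, self.total_length)
        idx = np.clip(np.searchsorted(self.cum, s, side="right") - 1,
                      0, len(self.segments) - 1)
        return s, idx

    def point(self, s):
        s, idx = self._locate(s)
        out = np.empty(np.shape(s) + (2,))
        for i, seg in enumerate(self.segments):
            sel = idx == i
            if np.any(sel):
                out[sel] = seg.point(np.asarray(s)[sel] - self.cum[i])
        return out

    def tangent(self, s):
        s, idx = self._locate(s)
        out = np.empty(np.shape(s) + (2,))
        for i, seg in enumerate(self.segments):
            sel = idx == i
            if np.any(sel):
                out[sel] = seg.tangent(np.asarray(s)[sel] - self.cum[i])
        return out


def _build_planar_path(spec: ArchSpec) -> _PlanarPath:
    """2D arch path in (h, z): h runs from +W/2 (AAo) to -W/2 (DAo).

    The ascending and descending limbs are straight and splay outward
    from the arch top, so the vertex angle between the apex-to-inlet and
    apex-to-outlet directions is controlled by width vs height.  A zero
    ``transverse_length`` gives a pointed-to-round top depending on the
    apex rounding radius (gothic: small, roman: large); a positive one
    inserts a flat transverse segment between two corner arcs (crenel).
    """
    W, H, Lt = spec.arch_width, spec.arch_height, spec.transverse_length
    ra = spec.apex_round_radius
    if Lt == 0:
        # straight limbs meeting at a rounded apex
        apex = np.array([0.0, H])
        inlet_corner = np.array([W / 2, 0.0])
        outlet_corner = np.array([-W / 2, 0.0])
        half = np.arctan2(W / 2, H)    # half of the apex interior angle
        d = ra / np.sin(half)          # apex -> arc centre distance
        lt = ra / np.tan(half)         # apex -> tangent point along limb
        up1 = (apex - inlet_corner)
        L1 = float(np.hypot(*up1))
        up1 = up1 / L1
        up2 = (outlet_corner - apex)
        up2 = up2 / float(np.hypot(*up2))
        if lt >= L1:
            raise PhantomError("apex_round_radius too large for the limbs")
        t1 = apex - lt * up1
        t2 = apex + lt * up2
        c = apex - np.array([0.0, d])
        a0 = np.arctan2(t1[1] - c[1], t1[0] - c[0])
        a1 = np.arctan2(t2[1] - c[1], t2[0] - c[0])
        inlet = inlet_corner - spec.aao_extension * up1
        outlet = outlet_corner + spec.dao_extension * up2
        return _PlanarPath([_Line(inlet, t1), _Arc(c, ra, a0, a1),
                            _Line(t2, outlet)])
    # crenel: splayed limbs, corner arcs, flat transverse top
    if Lt >= W:
        raise PhantomError("transverse_length must be < arch_width")
    A = np.array([W / 2, 0.0])
    top1 = np.array([Lt / 2, H])
    u1 = top1 - A
    u1 = u1 / float(np.hypot(*u1))
    # corner circle centre (hc, H - ra) tangent to the limb line and z=H
    hc = W / 2 + ((H - ra) * u1[0] - ra) / u1[1]
    if hc <= 0:
        raise PhantomError("corner radius too large for the transverse segment")
    C1 = np.array([hc, H - ra])
    t_par = float((C1 - A) @ u1)
    T1 = A + t_par * u1
    a0 = np.arctan2(T1[1] - C1[1], T1[0] - C1[0])
    inlet = A - spec.aao_extension * u1
    # mirrored descending side
    B = np.array([-W / 2, 0.0])
    u2 = B - np.array([-Lt / 2, H])
    u2 = u2 / float(np.hypot(*u2))
    C2 = np.array([-hc, H - ra])
    T2 = np.array([-T1[0], T1[1]])
    a1 = np.arctan2(T2[1] - C2[1], T2[0] - C2[0])
    outlet = B + spec.dao_extension * u2
    return _PlanarPath([
        _Line(inlet, T1),
        _Arc(C1, ra, a0, np.pi / 2),
        _Line((hc, H), (-hc, H)),
        _Arc(C2, ra, np.pi / 2, a1),
        _Line(T2, outlet),
    ])


# --------------------------------------------------------------------------
# Analytic centerline
# --------------------------------------------------------------------------

@dataclass
class _Branch:
    arc_position: float
    origin: np.ndarray
    direction: np.ndarray
    length: float
    radius: float
    angle_deg: float


class AnalyticCenterline:
    """Continuous arch centerline with exact tangents and radii.

    The main path runs inlet (ascending aorta) to outlet (descending
    aorta); branches are straight take-offs realizing the requested
    angles exactly in the continuous model.
    """

    def __init__(self, spec: ArchSpec):
        self.spec = spec
        self._path = _build_planar_path(spec)
        phi = np.deg2rad(spec.ap_tilt_deg)
        # in-plane horizontal axis (AP at zero tilt) and plane normal
        self._hhat = np.array([np.sin(phi), np.cos(phi), 0.0])
        self._nhat = np.array([np.cos(phi), -np.sin(phi), 0.0])
        self._R = np.eye(3) if spec.rotation is None else np.asarray(spec.rotation)
        total = self._path.total_length
        for pos in spec.branch_arc_positions[: spec.n_branches]:
            if not (0 < pos < total):
                raise PhantomError(
                    f"branch arc position {pos} outside path length {total:.1f}")
        self.branches = [self._make_branch(i) for i in range(spec.n_branches)]

    # -- embedding -------------------------------------------------------
    def _embed(self, hz: np.ndarray) -> np.ndarray:
        pts = hz[..., 0:1] * self._hhat[None, :] + hz[..., 1:2] * np.array(
            [0.0, 0.0, 1.0])[None, :]
        return pts @ self._R.T

    @property
    def total_length(self) -> float:
        return self._path.total_length

    def point(self, s) -> np.ndarray:
        return self._embed(self._path.point(s))

    def tangent(self, s) -> np.ndarray:
        t = self._embed(self._path.tangent(s))
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def radius(self, s) -> np.ndarray:
        """Lumen radius (mm) along the main path.

        Level radii blend smoothly (1.5 mm half-width) at the branch
        take-offs; the isthmus is a Gaussian dip past the last branch.
        """
        s = np.asarray(s, dtype=float)
        r = self.spec.lumen_radii
        arcs = [b.arc_position for b in self.branches]
        if self.spec.bovine:
            levels = [r["aao"], r["distal_arch"], r["dao"]]
        else:
            levels = [r["aao"], r["prox_arch"], r["distal_arch"], r["dao"]]
        out = np.full(np.shape(s), levels[0], dtype=float)
        for a, (lo, hi) in zip(arcs, zip(levels[:-1], levels[1:])):
            out = out + (hi - lo) * _smoothstep((s - a) / 1.5)
        c = arcs[-1] + self.spec.isthmus_offset
        out = out + (r["isthmus"] - r["dao"]) * np.exp(
            -((s - c) ** 2) / (2 * self.spec.isthmus_sigma ** 2)) * (s > arcs[-1])
        return out

    # -- branches --------------------------------------------------------
    def _make_branch(self, i: int) -> _Branch:
        spec = self.spec
        pos = float(spec.branch_arc_positions[i])
        alpha = np.deg2rad(spec.branch_angles[i])
        beta = np.deg2rad(spec.branch_azimuths[i])
        t = self.tangent(np.array([pos]))[0]
        n = -self._R @ self._nhat     # chosen so a 90 deg branch points superiorly
        up = np.cross(n, t)           # superior, in the arch plane
        lat = np.cross(t, up)         # lateral (out of plane)
        # take-off angle alpha to the tangent is preserved for any azimuth
        d = np.cos(alpha) * t + np.sin(alpha) * (np.cos(beta) * up
                                                 + np.sin(beta) * lat)
        d = d / np.linalg.norm(d)
        return _Branch(pos, self.point(np.array([pos]))[0], d,
                       spec.branch_length, spec.branch_radii[i],
                       spec.branch_angles[i])

    # -- sampling --------------------------------------------------------
    def sample_main(self, step: float = 0.25):
        s = np.arange(0.0, self.total_length, step)
        if self.total_length - s[-1] > 1e-6:
            s = np.append(s, self.total_length)
        return s, self.point(s), self.tangent(s), self.radius(s)

    def sample_branch(self, i: int, step: float = 0.25):
        b = self.branches[i]
        s = np.arange(0.0, b.length + step / 2, step)
        pts = b.origin[None, :] + s[:, None] * b.direction[None, :]
        return s, pts, b

    def apex(self) -> np.ndarray:
        s, pts, _, _ = self.sample_main(0.05)
        z = pts[:, 2]
        top = np.nonzero(z >= z.max() - 1e-9)[0]
        return pts[top[len(top) // 2]]

    def arch_angle_analytic(self, dao_offset: float = 20.0) -> float:
        """Closed-form arch angle of the continuous model (degrees)."""
        apex = self.apex()
        inlet = self.point(np.array([0.0]))[0]
        s_ref = min(self.branches[-1].arc_position + dao_offset,
                    self.total_length)
        ref = self.point(np.array([s_ref]))[0]
        v1, v2 = inlet - apex, ref - apex
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))

    def branch_span_analytic(self) -> float:
        return float(np.linalg.norm(self.branches[-1].origin - self.branches[0].origin))

    def to_tree(self, step: float = 0.5) -> CenterlineTree:
        """Exact centerline as a sampled :class:`CenterlineTree`."""
        s, pts, _, rad = self.sample_main(step)
        bifs = []
        names = (["trunk", "lsa"] if self.spec.bovine else ["bca", "lcca", "lsa"])
        for i, b in enumerate(self.branches):
            bs, bpts, _ = self.sample_branch(i, step)
            bifs.append(Bifurcation(b.arc_position, b.origin.copy(), bpts, bs,
                                    name=names[i]))
        return CenterlineTree(pts, s, rad, bifs, bovine=self.spec.bovine)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp: 0 for x <= -1, 1 for x >= 1."""
    t = np.clip((np.asarray(x, float) + 1) / 2, 0.0, 1.0)
    return t * t * (3 - 2 * t)


def _solve_branch_positions(spec: ArchSpec, span: float,
                            center_shift: float = 0.0) -> tuple:
    """Arc positions of the branch cluster realizing a chord span.

    Branches are spread symmetrically (in arc length) around the arch-top
    midpoint (shifted by ``center_shift`` toward the ascending side) so
    that the straight-line distance between the first and last take-off
    equals ``span``; the middle branch sits at the cluster centre.
    """
    probe = AnalyticCenterline(replace(
        spec, branch_arc_positions=tuple(
            spec.branch_arc_positions[: spec.n_branches])))
    path = probe._path
    sfine = np.linspace(0, path.total_length, 4001)
    z = path.point(sfine)[:, 1]
    top = np.nonzero(z >= z.max() - 1e-9)[0]
    s_top = sfine[top[len(top) // 2]] + center_shift

    def chord(delta):
        p = probe.point(np.array([s_top - delta, s_top + delta]))
        return np.linalg.norm(p[1] - p[0])

    if span <= 0:
        delta = 0.05
    else:
        lo, hi = 1e-3, min(s_top - 1.0, path.total_length - s_top - 1.0)
        if chord(hi) < span:
            raise PhantomError("requested branch span does not fit on the arch")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if chord(mid) < span:
                lo = mid
            else:
                hi = mid
        delta = 0.5 * (lo + hi)
    if spec.bovine:
        return (s_top - delta, s_top + delta)
    return (s_top - delta, s_top, s_top + delta)


def build_arch_centerline(spec: ArchSpec) -> AnalyticCenterline:
    """Analytic centerline (main path + branch take-offs) for ``spec``.

    Geometry is fully determined by the spec; the seed only affects flow
    and cohort generation.
    """
    return AnalyticCenterline(spec)


# --------------------------------------------------------------------------
# Voxelization
# --------------------------------------------------------------------------

def voxelize_arch(centerline: AnalyticCenterline, spacing: float = 0.5,
                  pad: float = 2.0, step: Optional[float] = None,
                  return_mesh: bool = False):
    """Rasterize the tube model onto a regular grid.

    A voxel belongs to the lumen iff its centre lies within the local
    tube radius of the centerline (implemented as a union of spheres
    along a dense sampling of all paths).  Raises
    :class:`ResolutionError` when ``spacing`` exceeds the smallest branch
    radius, i.e. when the lumen would not be resolved.
    """
    spec = centerline.spec
    min_radius = min(min(spec.branch_radii[: spec.n_branches]),
                     min(spec.lumen_radii.values()))
    if spacing > min_radius:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse for minimum radius {min_radius} mm")
    if step is None:
        step = min(0.25, spacing / 2)

    centers, radii = [], []
    s, pts, _, rad = centerline.sample_main(step)
    centers.append(pts)
    radii.append(rad)
    for i in range(len(centerline.branches)):
        _, bpts, b = centerline.sample_branch(i, step)
        centers.append(bpts)
        radii.append(np.full(len(bpts), b.radius))
    centers = np.concatenate(centers)
    radii = np.concatenate(radii)

    rmax = radii.max()
    lo = centers.min(axis=0) - rmax - pad
    hi = centers.max(axis=0) + rmax + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo
    data = np.zeros(shape, dtype=bool)

    for c, r in zip(centers, radii):
        i0 = np.floor((c - r - origin) / spacing).astype(int)
        i1 = np.ceil((c + r - origin) / spacing).astype(int) + 1
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, shape)
        ax = [origin[k] + np.arange(i0[k], i1[k]) * spacing - c[k] for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r

    mask = VoxelMask(data, np.full(3, spacing), origin)
    if not return_mesh:
        return mask
    mesh = _mask_to_mesh(mask)
    return mask, mesh


def _mask_to_mesh(mask: VoxelMask):
    import trimesh
    from skimage import measure
    padded = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(mask.spacing))
    verts = verts + (mask.origin - mask.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    return mesh


# --------------------------------------------------------------------------
# Flow synthesis
# --------------------------------------------------------------------------

def synthesize_flow(mask: VoxelMask, centerline: AnalyticCenterline,
                    flow_spec: FlowSpec) -> VelocityField4D:
    """Pulsatile kinematic velocity field on the phantom lumen.

    Per frame the axial component follows a Poiseuille profile scaled so
    the prescribed instantaneous inlet flux is reproduced; the helical
    component adds ``helix_ratio`` times the local axial speed
    tangentially about the centerline (right-handed for positive ratio);
    an optional vortex adds an in-plane solid-body rotation patch.
    Branch lumen voxels (beyond the main tube) carry zero velocity: the
    phantom prescribes arch hemodynamics, not branch run-off.
    """
    spec = flow_spec
    s, pts, tans, rad = centerline.sample_main(0.25)
    tree = cKDTree(pts)

    vox = mask.voxel_centers()
    dist, idx = tree.query(vox, workers=-1)
    local_r = rad[idx]
    in_main = dist <= local_r + 0.75 * float(np.max(mask.spacing))
    vi = vox[in_main]
    ii = idx[in_main]
    t_hat = tans[ii]
    r_vec = vi - pts[ii]
    r_ax = np.sum(r_vec * t_hat, axis=1, keepdims=True)
    r_perp = r_vec - r_ax * t_hat
    d_perp = np.linalg.norm(r_perp, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = np.where(d_perp[:, None] > 1e-9, r_perp / d_perp[:, None], 0.0)
    R = local_r[in_main]
    profile = np.clip(1.0 - (d_perp / R) ** 2, 0.0, None)
    # tangential unit field of a right-handed screw about the tangent;
    # the swirl ramps linearly to zero at the axis (a tangential speed
    # that stays finite on the axis would mean unbounded angular rate)
    tau = np.cross(t_hat, r_hat)
    swirl_ramp = np.clip(d_perp / (0.3 * R), 0.0, 1.0)

    vortex_gain = np.zeros(len(vi))
    vortex_dir = np.zeros_like(vi)
    if spec.vortex is not None:
        vx = spec.vortex
        c_v = centerline.point(np.array([vx["arc_center"]]))[0]
        a_v = centerline.tangent(np.array([vx["arc_center"]]))[0]
        dv = vi - c_v[None, :]
        ax_off = dv @ a_v
        dperp_v = dv - ax_off[:, None] * a_v[None, :]
        dv_norm = np.linalg.norm(dperp_v, axis=1)
        core = float(vx["core_radius"])
        inside = (dv_norm <= core) & (np.abs(ax_off) <= core)
        taper = np.cos(np.pi * ax_off / (2 * core)) ** 2
        # solid-body: speed = strength * (d/core), tapered axially
        vortex_gain[inside] = (float(vx["strength"]) * dv_norm[inside] / core
                               * taper[inside])
        with np.errstate(invalid="ignore", divide="ignore"):
            dhat_v = np.where(dv_norm[:, None] > 1e-9,
                              dperp_v / dv_norm[:, None], 0.0)
        vortex_dir = np.cross(np.broadcast_to(a_v, vi.shape), dhat_v)

    tfrac = (np.arange(spec.n_frames) + 0.5) / spec.n_frames
    wave = waveform(tfrac, spec.time_to_peak, spec.systolic_fraction)
    flux = spec.peak_flux * wave  # ml/s

    shape4 = (spec.n_frames,) + mask.data.shape
    u = np.zeros(shape4, dtype=np.float32)
    v = np.zeros(shape4, dtype=np.float32)
    w = np.zeros(shape4, dtype=np.float32)
    lin_idx = np.flatnonzero(mask.data.ravel())[in_main]
    rng = np.random.default_rng(spec.seed)
    noise_idx = np.flatnonzero(mask.data.ravel())

    exceeded = False
    for k in range(spec.n_frames):
        # mean axial speed (cm/s) from flux (ml/s) and area (mm^2)
        v_mean = 100.0 * flux[k] / (np.pi * R ** 2)
        v_ax = 2.0 * v_mean * profile
        vel = v_ax[:, None] * t_hat
        if spec.helix_ratio != 0.0:
            vel = vel + (spec.helix_ratio * v_ax * swirl_ramp)[:, None] * tau
        if spec.vortex is not None:
            vel = vel + (wave[k] * vortex_gain)[:, None] * vortex_dir
        frame = np.zeros((mask.data.size, 3), dtype=np.float32)
        frame[lin_idx] = vel
        if spec.noise_sd > 0:
            frame[noise_idx] += rng.normal(
                0.0, spec.noise_sd, size=(len(noise_idx), 3)).astype(np.float32)
        if np.any(np.abs(frame) > spec.venc):
            exceeded = True
            if spec.clip_to_venc:
                np.clip(frame, -spec.venc, spec.venc, out=frame)
        u[k] = frame[:, 0].reshape(mask.data.shape)
        v[k] = frame[:, 1].reshape(mask.data.shape)
        w[k] = frame[:, 2].reshape(mask.data.shape)

    meta = {"venc": spec.venc, "heart_rate": spec.heart_rate,
            "units": "cm/s", "venc_exceeded": bool(exceeded),
            "venc_clipped": bool(exceeded and spec.clip_to_venc)}
    if exceeded and not spec.clip_to_venc:
        warnings.warn("synthesized speeds exceed venc; aliasing would occur "
                      "in an acquisition", UserWarning, stacklevel=2)
    return VelocityField4D(u, v, w, mask.spacing.copy(), spec.frame_duration,
                           mask, flux_curve=flux, meta=meta)


def measure_inlet_flux(field: VelocityField4D,
                       centerline: AnalyticCenterline,
                       s_inlet: float = 3.0, extent: float = 8.0,
                       step: float = 0.25) -> np.ndarray:
    """Volume flux (ml/s) through the plane normal to the inlet tangent."""
    c = centerline.point(np.array([s_inlet]))[0]
    t = centerline.tangent(np.array([s_inlet]))[0]
    e1 = np.cross(t, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(t, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    g = np.arange(-extent, extent + step / 2, step)
    G1, G2 = np.meshgrid(g, g, indexing="ij")
    pts = c[None, :] + G1.ravel()[:, None] * e1 + G2.ravel()[:, None] * e2
    idx = field.lumen_mask.world_to_index(pts).T
    out = np.zeros(field.n_frames)
    for k in range(field.n_frames):
        vn = (map_coordinates(field.u[k], idx, order=1) * t[0]
              + map_coordinates(field.v[k], idx, order=1) * t[1]
              + map_coordinates(field.w[k], idx, order=1) * t[2])
        # cm/s * mm^2 -> ml/s requires /100
        out[k] = vn.sum() * step * step / 100.0
    return out


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def resample_mask(mask: VoxelMask, new_spacing) -> VoxelMask:
    """Nearest-neighbour resampling covering the same physical extent."""
    new_spacing = np.broadcast_to(np.asarray(new_spacing, float), (3,)).copy()
    if np.allclose(new_spacing, mask.spacing):
        return mask.copy()
    extent = (np.array(mask.data.shape) - 1) * mask.spacing
    shape = np.floor(extent / new_spacing).astype(int) + 1
    grids = [mask.origin[k] + np.arange(shape[k]) * new_spacing[k]
             for k in range(3)]
    coords = np.meshgrid(*[(g - mask.origin[k]) / mask.spacing[k]
                           for k, g in enumerate(grids)], indexing="ij")
    data = map_coordinates(mask.data.astype(np.float32), coords, order=0) >= 0.5
    return VoxelMask(data, new_spacing, mask.origin.copy())


def resample_field(field: VelocityField4D, new_spacing) -> VelocityField4D:
    """Trilinear resampling of each component, per frame.

    The lumen mask is resampled by nearest neighbour; the new grid covers
    the same physical extent.  Resampling to the identical spacing
    returns an unchanged copy.
    """
    new_spacing = np.broadcast_to(np.asarray(new_spacing, float), (3,)).copy()
    if np.any(new_spacing <= 0):
        raise PhantomError("new_spacing must be positive")
    if np.allclose(new_spacing, field.spacing):
        return field.copy()
    new_mask = resample_mask(field.lumen_mask, new_spacing)
    shape = new_mask.data.shape
    coords = np.meshgrid(*[(np.arange(shape[k]) * new_spacing[k])
                           / field.spacing[k] for k in range(3)],
                         indexing="ij")
    comps = []
    for arr in (field.u, field.v, field.w):
        out = np.empty((field.n_frames,) + shape, dtype=np.float32)
        for k in range(field.n_frames):
            out[k] = map_coordinates(arr[k].astype(np.float64), coords, order=1)
        comps.append(out)
    return VelocityField4D(comps[0], comps[1], comps[2], new_spacing,
                           field.frame_duration, new_mask,
                           None if field.flux_curve is None
                           else np.array(field.flux_curve),
                           dict(field.meta))


def mirror_field(field: VelocityField4D, axis: int = 0) -> VelocityField4D:
    """Reflect the field (grid and vectors) across a grid plane.

    Mirroring flips the handedness of any helical component; the
    downstream helix scores must swap right/left exactly.
    """
    flip = [slice(None)] * 4
    flip[axis + 1] = slice(None, None, -1)
    flip = tuple(flip)
    comps = [field.u[flip].copy(), field.v[flip].copy(), field.w[flip].copy()]
    comps[axis] = -comps[axis]
    mask = VoxelMask(np.flip(field.lumen_mask.data, axis=axis).copy(),
                     field.lumen_mask.spacing.copy(),
                     field.lumen_mask.origin.copy())
    return VelocityField4D(comps[0], comps[1], comps[2],
                           field.spacing.copy(), field.frame_duration, mask,
                           None if field.flux_curve is None
                           else np.array(field.flux_curve),
                           dict(field.meta))


# --------------------------------------------------------------------------
# Synthetic cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Synthetic two-group cohort (no re-CoA vs re-CoA).

    ``continuous_effects`` maps endpoint name to ``(mean, sd, shift)``:
    values are normal with the given mean/sd in the no-re-CoA group and
    mean+shift in the re-CoA group.  ``binary_effects`` maps name to
    ``(p_no_recoa, p_recoa)``.
    """

    n_no_recoa: int = 24
    n_recoa: int = 4
    continuous_effects: dict = field(default_factory=dict)
    binary_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_no_recoa < 1 or self.n_recoa < 1:
            raise PhantomError("group sizes must be >= 1")
        for name, (p0, p1) in self.binary_effects.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise PhantomError(f"probabilities for {name!r} must be in [0,1]")


#: endpoint taxonomy mirroring the group-comparison table of a
#: post-repair arch cohort (null effects; tests override shifts).
DEFAULT_COHORT_ENDPOINTS = {
    "continuous": {
        "arch_angle_deg": (110.0, 10.0, 0.0),
        "branch_span_mm": (8.0, 3.0, 0.0),
        "caliber_aao_to_distal": (1.1, 0.5, 0.0),
        "lh_helix_systole": (0.05, 0.02, 0.0),
        "rh_helix_diastole": (0.08, 0.03, 0.0),
        "vortex_cycle": (0.12, 0.04, 0.0),
    },
    "binary": {
        "thoracotomy": (0.4, 0.4),
        "bav": (0.6, 0.6),
    },
}


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject endpoint table with a binary re-CoA label.

    Deterministic under ``spec.seed``; endpoints default to the
    null-effect taxonomy in :data:`DEFAULT_COHORT_ENDPOINTS` when the
    spec lists none.
    """
    cont = spec.continuous_effects or DEFAULT_COHORT_ENDPOINTS["continuous"]
    binr = spec.binary_effects or (
        {} if spec.continuous_effects else DEFAULT_COHORT_ENDPOINTS["binary"])
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_no_recoa, spec.n_recoa
    group = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    data = {"recoa": group}
    for name, (mean, sd, shift) in cont.items():
        data[name] = rng.normal(mean + shift * group, sd)
    for name, (p0, p1) in binr.items():
        p = np.where(group == 1, p1, p0)
        data[name] = (rng.random(n0 + n1) < p).astype(int)
    return pd.DataFrame(data)
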