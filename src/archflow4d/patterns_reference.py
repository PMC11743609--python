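"""Naive per-voxel reference implementation of the pattern scores.

This module computes the vortex and helix scores directly from their
definitions with an explicit Python loop over voxels and neighbour
gathering, with no shared accumulators.  It exists as an independent
cross-check for the optimized implementation in :mod:`.patterns` and is
far too slow for production use.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .core import VelocityField4D
from .patterns import (PatternMatchParams, ScoreMaps, _sphere_offsets,
                       _vorticity)
from .phantom import resample_field

__all__ = ["pattern_maps_reference"]


def pattern_maps_reference(fld: VelocityField4D,
                           params: Optional[PatternMatchParams] = None
                           ) -> ScoreMaps:
    """Slow direct evaluation of the vortex / helix score definitions."""
    params = params or PatternMatchParams()
    fld = resample_field(fld, params.iso_spacing)
    lumen = fld.lumen_mask.data
    offsets, disp, wgt = _sphere_offsets(params)
    shape = lumen.shape
    shape4 = (fld.n_frames,) + shape
    vort = np.zeros(shape4, dtype=np.float32)
    rh = np.zeros(shape4, dtype=np.float32)
    lh = np.zeros(shape4, dtype=np.float32)
    voxels = np.argwhere(lumen)
    eps = 1e-12
    for t in range(fld.n_frames):
        U = np.stack([fld.u[t], fld.v[t], fld.w[t]], axis=-1).astype(float)
        om = np.moveaxis(
            _vorticity(U[..., 0], U[..., 1], U[..., 2], fld.spacing), 0, -1)
        om_mag = np.linalg.norm(om, axis=-1)
        lm = om_mag[lumen]
        floor = (params.vorticity_floor * np.percentile(lm, 95)
                 if lm.size else 0.0)
        for p in voxels:
            q = p[None, :] + offsets
            ok = np.all((q >= 0) & (q < np.array(shape)[None, :]), axis=1)
            q = q[ok]
            inl = lumen[q[:, 0], q[:, 1], q[:, 2]]
            q = q[inl]
            if len(q) == 0:
                continue
            d = disp[ok][inl]
            w = wgt[ok][inl]
            u = U[q[:, 0], q[:, 1], q[:, 2]]
            pt = tuple(p)
            # vortex score about the vorticity axis; velocities taken
            # relative to the local weighted mean (advection-corrected)
            if om_mag[pt] > max(floor, eps):
                axis = om[pt] / om_mag[pt]
                ubar = np.sum(w[:, None] * u, axis=0) / np.sum(w)
                uc = u - ubar[None, :]
                tmpl = np.cross(np.broadcast_to(axis, d.shape), d)
                num = float(np.sum(w * np.sum(uc * tmpl, axis=1)))
                den = np.sqrt(float(np.sum(w * np.sum(uc * uc, axis=1)))
                              * float(np.sum(w * np.sum(tmpl * tmpl,
                                                        axis=1))))
                if den > eps:
                    vort[t][pt] = np.clip(num / den, 0.0, 1.0)
            # signed helix score about the mean-flow axis
            m = np.sum(w[:, None] * u, axis=0)
            sw = float(np.sum(w))
            if sw > eps and np.linalg.norm(m) / sw \
                    > params.axial_speed_floor:
                axis = m / np.linalg.norm(m)
                u_ax = (u @ axis)[:, None] * axis[None, :]
                u_perp = u - u_ax
                tmpl = np.cross(np.broadcast_to(axis, d.shape), d)
                num = float(np.sum(w * np.sum(u_perp * tmpl, axis=1)))
                den = np.sqrt(float(np.sum(w * np.sum(u * u, axis=1)))
                              * float(np.sum(w * np.sum(tmpl * tmpl,
                                                        axis=1))))
                if den > eps:
                    s = num / den
                    rh[t][pt] = np.clip(s, 0.0, 1.0)
                    lh[t][pt] = np.clip(-s, 0.0, 1.0)
    return ScoreMaps(vort, rh, lh, lumen.copy(), fld.spacing.copy())
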