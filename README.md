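# archflow4d

Aortic-arch geometry and 4D-flow pattern analysis for post-operative
neonatal coarctation studies — with a synthetic phantom layer so the
whole pipeline runs and is tested without any patient data.

After surgical repair of aortic coarctation, the reshaped arch (round
"roman", rectangular "crenel", or pointed "gothic") changes the blood
flow through the transverse arch and isthmus, and both geometry and
flow have been linked to recurrent coarctation (re-CoA).  This package
implements the quantitative layer of such a study:

* **Synthetic phantoms** (`archflow4d.phantom`) — analytic arch
  centerlines for the three morphologies with three supra-aortic
  branches (or a bovine common trunk), voxelized lumen masks emulating
  0.5 mm black-blood segmentations, and pulsatile three-component
  velocity fields with controlled axial, helical (signed handedness)
  and vortical content.  Because the generator is analytic, every
  downstream measurement has exact ground truth.
* **Arch morphometry** (`archflow4d.geometry`) — mask conditioning
  (resample to 0.5 mm, one-voxel dilation, 0.9 mm Gaussian smoothing),
  centerline-tree extraction by 3D thinning plus wall-based
  re-centering, and the endpoint set: bifurcation angles between branch
  and arch tangents, the apex-vertex angle between ascending and
  descending aorta, anteroposterior arch angulation, the span between
  the first and last branching points, cross-sectional areas at the
  ascending aorta / proximal arch / distal arch / isthmus, the derived
  caliber ratios `A_AAo / A_level`, and a quantitative roman / crenel /
  gothic classification.
* **Flow pattern scoring** (`archflow4d.patterns`) — per voxel `p` and
  frame, the velocity neighbourhood `N(p) = {q : |q - p| <= R}`
  (R = 2.75 mm on a 1 mm isotropic grid) is matched against an
  idealized rotational template `t(q) = a x (q - p)`:

      s(p) = sum_q w(q) u(q) . t(q)
             / sqrt( sum_q w(q) |u(q)|^2 * sum_q w(q) |t(q)|^2 )

  with `a` the local vorticity direction (vortex score,
  advection-corrected) or the weighted mean flow direction (helix
  score, signed by the right-hand rule into right- and left-handed
  channels).  ROI-mean score curves over the distal arch (just past the
  left carotid take-off to 2 cm beyond the left subclavian) are reduced
  to cycle / systole / diastole means and peak, and a
  resolution-sensitivity study compares acquisitions at 1 mm, 2 mm and
  the clinical protocol (2.4 x 3.6 x 1.5 mm).
* **Cohort statistics** (`archflow4d.stats`) — exact two-sided Fisher
  tests on 2x2 tables (log-space hypergeometric enumeration),
  Mann-Whitney U with an exact/asymptotic crossover, Pearson
  correlations, and a group-comparison report builder.
* **Orchestration** (`archflow4d.pipeline`, `archflow4d.io`) — a seeded
  end-to-end pipeline with byte-identical reports, and readers/writers
  for NIfTI masks, 4D velocity components with JSON sidecars, ASCII VTK
  centerlines, STL surfaces and CSV cohorts.

## Worked example

`examples/03_flow_patterns.py` synthesizes a pulsatile right-handed
corkscrew flow (tangential/axial ratio 0.4, plus a 25 cm/s vortex patch
in the distal arch) on a roman-arch phantom and scores it:

```
ROI: arc 20.9-43.7 mm, 720 voxels; systole = frames [1, 2]
pattern      cycle  systole  diastole   peak
vortex       0.173    0.401     0.115  0.403
rh_helix     0.069    0.175     0.042  0.175
lh_helix     0.000    0.000     0.000  0.000
```

Each number is a 0-1 pattern-match score averaged over the distal-arch
region of interest and the named phase: the field scores only in the
right-handed helix channel (it is a right-handed screw), the vortex
patch dominates systole, and everything vanishes in diastole where the
prescribed inlet flux is zero.  The other examples cover phantom
construction (`01`), full morphometry with ground-truth comparison
(`02`), the resolution study (`04`) and the statistics layer (`05`);
each prints what it computes and what the numbers mean.

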