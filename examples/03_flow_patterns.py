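"""Score helical and vortical flow in the distal arch of a phantom.

Synthesizes a pulsatile right-handed corkscrew flow (tangential speed
0.4 of axial) with a vortex patch in the distal arch, scores every
voxel and frame against the vortex / helix templates, and prints the
region-of-interest summaries: each value is a 0-1 pattern-match score
averaged over the distal-arch ROI and the named phase of the cycle.
"""
import numpy as np

from archflow4d import (ArchSpec, FlowSpec, build_arch_centerline,
                        build_roi, pattern_maps, summarize, synthesize_flow,
                        voxelize_arch)

spec = ArchSpec.canonical("roman")
cl = build_arch_centerline(spec)
mask = voxelize_arch(cl, spacing=1.0)
tree = cl.to_tree(0.25)

flow = synthesize_flow(mask, cl, FlowSpec(
    helix_ratio=0.4, noise_sd=1.5, n_frames=10, seed=7,
    vortex={"arc_center": tree.bifurcations[-1].arc_position + 8.0,
            "strength": 25.0, "core_radius": 3.0}))

maps = pattern_maps(flow)          # resamples to 1 mm iso and scores
roi = build_roi(tree, flow.lumen_mask)
summary = summarize(maps, roi, flow.flux_curve)

print(f"ROI: arc {roi.start_mm:.1f}-{roi.end_mm:.1f} mm, "
      f"{len(roi.voxels)} voxels; systole = frames "
      f"{summary.systole_frames.tolist()}")
print(f"{'pattern':10s} {'cycle':>7s} {'systole':>8s} "
      f"{'diastole':>9s} {'peak':>6s}")
for name in ("vortex", "rh_helix", "lh_helix"):
    v = summary[name]
    print(f"{name:10s} {v['cycle_mean']:7.3f} {v['systole_mean']:8.3f} "
          f"{v['diastole_mean']:9.3f} {v['peak']:6.3f}")
print("\nA right-handed screw scores only in the rh channel; scores rise")
print("with the swirl fraction of the motion and vanish in diastole,")
print("where the prescribed inlet flux (and the axial coherence) is zero.")
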