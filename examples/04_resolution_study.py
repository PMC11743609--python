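"""Resolution sensitivity of the pattern scores.

Acquires one phantom flow field at three voxel sizes (1 mm isotropic,
2 mm isotropic, and the clinical 4D-flow protocol 2.4 x 3.6 x 1.5 mm),
resamples everything back to 1 mm isotropic, rescores, and prints the
signed percent difference of each ROI-mean score curve against the
clinical protocol — the fine acquisition diverges most, because coarse
voxels smear rotational patterns over more of the lumen.
"""
from archflow4d import (ArchSpec, FlowSpec, build_arch_centerline,
                        run_resolution_study, synthesize_flow,
                        voxelize_arch)

spec = ArchSpec.canonical("roman")
cl = build_arch_centerline(spec)
mask = voxelize_arch(cl, spacing=1.0)
tree = cl.to_tree(0.25)

flow = synthesize_flow(mask, cl, FlowSpec(
    helix_ratio=0.3, noise_sd=1.0, n_frames=8, seed=3,
    vortex={"arc_center": tree.bifurcations[-1].arc_position + 8.0,
            "strength": 25.0, "core_radius": 3.0}))

table = run_resolution_study(flow, tree)
print(table.to_string(index=False,
                      float_format=lambda x: f"{x:8.1f}"))
print("\ndifference = 100 * mean_t(test - clinical) / mean_t(clinical);")
print("NaN marks a pattern that is absent from the reference scan.")
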