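"""Shrinkage bookkeeping and histology-to-microCT section matching.

First computes stage-to-stage shrinkage between preparation states (fresh,
fixed, dehydrated) under both reporting conventions; then matches a
rotated 2D query against a phantom volume by exhaustive NCC search.
"""

import numpy as np
from scipy import ndimage

import vascmorph as vm

rep = vm.shrinkage_report(
    [("fresh", 1000.0), ("fixed", 1090.0), ("dehydrated", 403.3)]
)
for pair in rep.pairs():
    print(f"{pair['from']} -> {pair['to']}: retained "
          f"{pair['retained_percent']:.0f}%, shrinkage "
          f"{pair['shrinkage_percent']:.0f}%")
scale = rep.cumulative_scale_factor()
print(f"cumulative isotropic linear scale factor: {scale:.3f}")

tree = vm.generate_vessel_tree(seed=4, tortuosity_amplitude_um=2.0)
vol, truth = vm.rasterize_tree(tree, voxel_size_um=2.0, noise_sigma=10.0, seed=7)
z = int(truth.data.sum(axis=(1, 2)).argmax())

query = ndimage.rotate(truth.data[z].astype(float), 10.0, reshape=False, order=0)
match = vm.match_section(
    query, vol, z_range=(max(z - 8, 0), z + 8),
    rotations_deg=np.arange(-14.0, 14.1, 2.0).tolist(),
)
print(f"true slice {z}; matched z={match.z_index}, "
      f"rotation correction {match.in_plane_rotation_deg:+.0f} deg, "
      f"NCC score {match.score:.3f}")
# the negative rotation exactly undoes the +10 deg applied to the query;
# the linear scale factor above is what shrunken histology sections must be
# multiplied by to overlay on the pre-shrinkage scan.
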