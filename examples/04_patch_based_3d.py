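"""Patch extraction and probability stitching for the direct (3D) path.

Tiles a phantom volume into overlapping 3D patches, pushes each through an
(untrained) 3D encoder-decoder, and stitches the per-patch probabilities
back into a full volume by averaging overlaps — the inference machinery of
direct volume estimation.
"""

import numpy as np

import strokevol as sv
from strokevol.seg import normalize_volume
from strokevol.unet import UNet, UNetConfig

spec = sv.PhantomSpec(
    matrix_size=64, n_slices=12, pixel_spacing_mm=(3.5, 3.5),
    slice_thickness_mm=3.0,
    lesions=(sv.LesionBlob(center_mm=(18.0, 110.0, 110.0), radii_mm=(12.0,) * 3),),
    noise_sigma=20.0, seed=3,
)
study, mask = sv.generate_phantom(spec)

patch_shape, stride = (16, 64, 64), (8, 32, 32)
patches = sv.extract_patches(normalize_volume(study.voxels), patch_shape, stride)
print(f"volume {study.shape} -> {len(patches)} patches of {patch_shape} "
      f"at stride {stride} (50% overlap)")

model = UNet(UNetConfig(dimensionality=3, depth=3, base_channels=8,
                        input_channels=1, seed=0))
prob_patches = [
    sv.Patch3D(voxels=model.forward(p.voxels[None, None])[0, 0], origin=p.origin)
    for p in patches
]
probs = sv.stitch_patches(prob_patches, study.shape)
print(f"stitched probability volume: shape {probs.shape}, "
      f"range [{probs.min():.3f}, {probs.max():.3f}]")

coverage = np.zeros(study.shape, dtype=int)
for p in patches:
    sl = tuple(slice(o, o + s) for o, s in zip(p.origin, p.voxels.shape))
    coverage[sl] += 1
print(f"every voxel covered by {coverage.min()}-{coverage.max()} patches")
# An untrained model emits probabilities near 0.5 everywhere; training (see
# example 03 and scripts/acceptance.py) is what separates lesion from brain.
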