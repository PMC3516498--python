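"""Build the default bilateral orbital phantom and check its ground truth.

The phantom is a CBCT-like volume (0.3 mm isotropic voxels) holding two
elliptic-cone bony cavities with adult orbital-rim dimensions (40 x 35 mm,
45 mm deep), wall openings standing in for the orbital fissures, and
additive Gaussian noise.  Every cross-section area and slab volume of the
cavity is known in closed form, which is what makes the downstream
measurement stages testable.
"""

from orbitovol import PhantomSpec, generate_phantom
from orbitovol.phantom import LABEL_CAVITY, label_volume

spec = PhantomSpec()
vol, gt = generate_phantom(spec)
labels, spacing, _ = label_volume(spec)

print(f"volume shape {vol.shape}, voxel spacing {spec.voxel_spacing} mm")
print(f"analytic rim cross-section : {gt.area('right', 0.0):8.1f} mm^2")
print(f"analytic full cavity volume: {gt.volume('right'):8.1f} mm^3")

voxel_volume = (labels == LABEL_CAVITY).sum() / 2 * spacing.prod()
err = 100 * (voxel_volume / gt.volume("right") - 1)
print(f"voxel-counted cavity volume: {voxel_volume:8.1f} mm^3  ({err:+.3f}% vs analytic)")
print("The voxelized cavity reproduces the closed-form cone volume; the")
print("small residual is the 0.3 mm discretization.")
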