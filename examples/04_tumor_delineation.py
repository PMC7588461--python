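"""Delineate a low-autofluorescence (tumor-like) region in 3D.

Pancreatic tumor tissue emits markedly less autofluorescence than normal
parenchyma, so after reconstruction a dark compact region inside the tissue
mask delineates it. Thin dark tubes (vessels, ducts) are rejected by shape
rules; the recovered mask is compared with the phantom's true ellipsoid.
"""

import numpy as np

from aftomo import (AcquisitionSpec, PhantomSpec, PreprocessParams, TumorEllipsoid,
                    cut_range, delineate_low_af_region, forward_project,
                    generate_phantom, reconstruct_volume, tissue_mask)

spec = PhantomSpec(
    shape_vox=(96, 96, 96), n_islets=40, n_vessels=2,
    islet_diameter_log_mu=np.log(70.0),
    tumor_ellipsoid=TumorEllipsoid(center_vox=(50, 46, 48),
                                   semi_axes_vox=(20, 17, 15),
                                   intensity_factor=0.4),
    seed=4)
volume, truth = generate_phantom(spec)
stack = cut_range(forward_project(volume, AcquisitionSpec(n_angles=160,
                                                          noise_model="none")),
                  PreprocessParams(clahe_enabled=False))
recon = reconstruct_volume(stack)
low = delineate_low_af_region(recon, mask=tissue_mask(recon))

true = truth.label_volume == 2
dice = 2 * np.logical_and(low, true).sum() / (low.sum() + true.sum())
vox_um3 = recon.voxel_size_scalar_um ** 3
print(f"true tumor volume:      {true.sum() * vox_um3 / 1e6:.2f} mm^3 x 1e-3")
print(f"recovered tumor volume: {low.sum() * vox_um3 / 1e6:.2f} mm^3 x 1e-3")
print(f"Dice overlap: {dice:.3f}")
# Dice near 1 and matching volumes mean the dark region found by the
# intensity split is the embedded tumor, not vessels or the specimen border.
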