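"""Estimate the center-of-rotation offset and reconstruct the volume.

A misaligned rotation axis doubles every structure in the reconstruction.
Conjugate (theta, theta+180 deg) projection pairs are mirror images about the
axis, so phase correlation of each mirrored pair recovers the offset to
sub-pixel precision; frames are then shifted and reconstructed by filtered
back-projection.
"""

import numpy as np

from aftomo import (AcquisitionSpec, PhantomSpec, PreprocessParams, apply_correction,
                    cut_range, estimate_cor, forward_project, generate_phantom,
                    reconstruct_volume)

volume, truth = generate_phantom(PhantomSpec(
    shape_vox=(64, 64, 64), n_islets=20, n_vessels=2,
    islet_diameter_log_mu=np.log(60.0), islet_diameter_log_sigma=0.3, seed=7))
stack = forward_project(volume, AcquisitionSpec(
    n_angles=120, cor_offset_px=2.5, noise_model="gaussian", noise_scale=0.02,
    seed=8))

stack = cut_range(stack, PreprocessParams(clahe_enabled=False))
result = estimate_cor(stack)
print(f"estimated COR offset: {result.cor_offset_px:+.2f} px (true +2.50 px)")

corrected = apply_correction(stack, result)
recon = reconstruct_volume(corrected)
r = np.corrcoef(recon.data.ravel(), volume.data.ravel())[0, 1]
print(f"reconstruction vs ground-truth volume: Pearson r = {r:.3f}")
# r close to 1 means the open FBP chain faithfully inverts the simulated scan;
# without the correction the doubled structures would depress it sharply.
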