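# Methods

This note documents the models, parameter choices, numerics and known
limitations of the `aftomo` pipeline. It is the place where design decisions
that were genuinely open are recorded, in the package's own terms.

## Forward model and geometry

The scanner is modelled as telecentric parallel-beam optics: a projection
frame at rotation angle θ is the discrete line integral of the volume along
the optical axis after rotating the volume by θ about the vertical (z) axis,
then shifting horizontally by the center-of-rotation (COR) offset. Frame
values are plain voxel sums (no path-length scaling); with this model,
filtered back-projection is the exact inverse in the noiseless dense-angle
limit, which is what makes quantitative parameter-recovery validation
possible.

Conventions: 0-based voxel indices in `(z, y, x)` order; rotation about z;
sub-pixel centers at `(n − 1) / 2`, so mirroring an array with `[::-1]`
reflects it exactly about the rotation center for any width parity. A point
at `(dy, dx)` from the center projects to detector coordinate
`dx·cosθ − dy·sinθ`, matching the classical Radon convention (and
`skimage.transform.radon` numerically, to machine precision at odd widths).

Rotation uses linear interpolation (`scipy.ndimage.affine_transform`,
out-of-field zero); matrix entries within 1e−12 of 0/±1 are snapped so
cardinal-angle rotations map grid points to grid points instead of
epsilon-outside-the-array coordinates. Sub-pixel horizontal shifts (COR
injection and correction) use exact Fourier phase ramps; frames are
effectively zero-bordered because the specimen sits inside the inscribed
circle, so periodic wrap-around is harmless.

## The synthetic phantom

The phantom emulates a cleared pancreas biopsy in the NIR autofluorescence
channel:

* **Tissue**: an ellipsoid with semi-axes (0.47, 0.455, 0.425) of the grid
  shape — slightly asymmetric like a real biopsy, and small enough
  transversally that rotation never clips tissue (mass conservation of the
  projections holds to <1%).
* **Islets**: spheres with lognormal diameters. The standard conditions are
  500 islets, lognormal(μ=ln 100 µm, σ=0.4), intensity 3.0 against
  parenchyma 1.0 on a 192³ grid of 10 µm voxels. A lognormal matches the
  right-skewed size distributions reported for human islets; the 3:1
  contrast is a configuration default, not a claim about tissue — the true
  islet:parenchyma AF ratio in the NIR channel is not established, and the
  parameter is exposed for that reason.
* **Vessels/ducts**: straight cylinders (default 4, radius 30 µm) of random
  orientation at 0.5× parenchyma intensity — dark tubes, as lumina are.
* **Tumor** (optional): an ellipsoid at `intensity_factor` < 1 times
  parenchyma (default 0.4), strictly darker than normal tissue.
* **Uneven illumination**: a smooth multiplicative field (random gradient
  plus a long-wavelength sine, amplitude default 0.15) applied to the whole
  tissue.
* **Noise** (acquisition): `gaussian` adds σ = `noise_scale` ×
  parenchyma-intensity to the projections; `poisson_gaussian` (default)
  first applies shot noise scaled so the relative photon noise at the
  brightest ray equals `noise_scale`, then the Gaussian term.

Placement is rejection sampling: centers drawn uniformly inside the tissue
ellipsoid shrunk by the islet radius (so spheres always fit), rejected on
overlap with vessels, the tumor, or other islets. Islets keep a ≥2-voxel
surface gap from each other — reconstruction blur bridges 1-voxel gaps at
segmentation thresholds, which would fuse distinct ground-truth objects —
and a ≥1-voxel gap from the (dark) vessels and tumor, where fusion is not a
hazard. Large islets are placed first, which eases packing without changing
the drawn diameter sample. Vessels avoid the tumor ellipsoid so every
ground-truth voxel has a single unambiguous label. The attempt budget is
10 × n_islets rejections; exceeding it raises an error naming the crowding
parameters.

What the phantom does **not** model: optical point-spread function and
light-sheet thickness, scattering, refractive-index mismatch, cone-beam
geometry, ring artifacts, and real tissue texture (parenchyma is flat apart
from the illumination field). Passing recovery tests therefore demonstrates
the correctness of the processing chain under the stated forward model, not
performance on real scanner data with uncorrected optics.

## Preprocessing

Range cutting computes global percentiles over the whole stack (defaults
1 / 99.5 — hot-pixel removal without flattening islet signal), clips, and
rescales linearly to [0, 1]. Being affine, it is safe for quantitative
intensities. CLAHE runs per frame (projections at different angles have
different content) on a 32 × 32-pixel tile grid with 256-bin histograms and
clip limit 0.01 in the fraction-of-tile-pixels convention, via
`skimage.exposure.equalize_adapthist`. Because CLAHE is non-linear, the
pipeline reconstructs from range-cut-only projections whenever the goal is
quantification (`clahe_enabled=False`); the CLAHE variant exists for
visualization and contrast-starved registration, and the preprocessing
variant used is recorded in each run's provenance.

## Alignment

For every conjugate pair, the θ+180° frame is mirrored about the detector
center and registered to the θ frame by upsampled DFT phase correlation
(default precision 0.1 px); half the horizontal shift is that pair's COR
estimate, and the median over pairs is the result. The median makes the
aggregate robust: corrupting 20% of frames with strong noise moves it by
≤0.2 px in the test suite.

Apodization before registration is **off by default**. A fixed window
multiplies the two frames of a pair at the same detector coordinates, so
after a shift the windowed images are no longer translates of each other;
measured bias reached 0.5–1 px at 5–16 px shifts, far above the 0.1 px
target, while the unwindowed estimator is exact because the frames already
vanish at their borders. A Hann window remains available (`window="hann"`)
for data whose frames are non-zero at the frame edge.

Estimates beyond a quarter of the frame width are refused as implausible.
Only the horizontal offset is modelled; detector tilt and per-frame jitter
are out of scope.

## Reconstruction

FBP with the discrete Ramachandran–Lakshminarayanan ramp kernel built in
real space (f[0] = 1/4, f[n] = −1/(πn)² for odd n), avoiding the DC bias of
a naive |f| ramp; optional Hann (default) or Shepp-Logan windows multiply
the frequency response. Full-rotation scans are folded to 180° by averaging
mirrored conjugate rays, halving work and averaging uncorrelated noise.
Back-projection is linear interpolation on the filtered rows, vectorized
across all z-sections, scaled by π/(2 n_angles); voxels outside the
inscribed circle are zeroed by default. On an analytically projected uniform
disc at 400 angles the interior mean is recovered within 0.3% and interior
nRMSE is ≈0.004; against `skimage.transform.iradon` the interior agrees to
machine precision (the implementations differ only in boundary masking).
No ring-artifact, beam-hardening or smoothing corrections are applied: AF
OPT has no beam hardening and the phantoms have no ring artifacts.

## Segmentation

**Tissue mask**: whole-volume Otsu threshold, largest 26-connected
component, morphological closing (ball radius 2), then hole filling — 3D
fill plus a per-axis 2D slice fill, because a dark inclusion (tumor, lumen)
can stay connected to the outside background through a thin low-intensity
channel that defeats a single 3D fill. All thresholds downstream are
computed inside this mask and are invariant to global linear intensity
rescaling.

**Baseline subtraction**: default is a normalized Gaussian convolution of
the in-mask intensities with σ = 200 µm — far above islet diameters, so the
smooth parenchyma plateau and the illumination field are removed while
islets keep ≈90% of their amplitude; the result is clipped at zero. A
constant-percentile variant exists. σ below 2 voxels is refused (it would
erase the objects themselves).

**Islet threshold**: the default is Otsu's between-class criterion with
*plateau centering*. After baseline subtraction most in-mask voxels are
exactly zero and the histogram has an empty gap below the islet mode; the
Otsu objective is flat across that gap and library implementations return
its bottom edge, which sweeps faint residual-background blobs into the
segmentation. Iterating the class-mean midpoint (the isodata fixed point)
from the Otsu start lands mid-gap, stays scale-invariant, and — because the
mid-amplitude crossing of a symmetrically blurred edge sits at the true
boundary — yields nearly unbiased bounding-box extents, which is what the
mean-diameter statistic needs. A k·σ alternative (k robust standard
deviations of the in-mask residual background, default k=4) is provided;
on near-noise-free reconstructions its threshold sits close to zero and
systematically inflates extents, which is why it is not the default.

Components below `min_voxels` (default 27 ≈ a 3-voxel-per-axis minimum
resolvable islet) are dropped exactly: 26 voxels is removed, 27 kept.
Connectivity is 26 by default so islets are not split across diagonal voxel
contacts.

**Artifact removal** is rule-based, standing in for manual curation: a
component is removed if its bounding-box elongation (longest/shortest
extent) exceeds 6 — stray hairs and tube fragments are thin and long — or
if its fill fraction (voxels / bounding-box voxels) falls below 0.2, which
catches diagonal or *crossing* tubes whose joint bounding box looks
deceptively compact (blobs score ≥0.5). Border-touching components can
optionally be excluded; a CSV of label ids supports manual exclusions.

**Low-AF (tumor) delineation**: inside the tissue mask eroded by 3 voxels
(the blurred specimen boundary would otherwise masquerade as a dark
region), intensities above the 90th in-mask percentile are set aside (so
sparse bright islets cannot dominate a two-class split) and an isodata
threshold separates dark from normal tissue. The dark class is accepted
only if its mean is ≤0.7 of the bright-class mean — otherwise it is just
the dark tail of parenchyma and an empty mask is returned with a warning
(a tumor-free specimen is a valid outcome). Surviving components pass the
voxel-number filter and the same shape rules (vessels and ducts are also
dark, but tubular); if the surviving volume is below 1% of the tissue the
result is again treated as tumor-free. The isodata threshold crosses the
blurred tumor boundary at its geometric edge, so recovered volumes are
nearly unbiased (≈+2% on the standard tumor phantom, Dice ≈0.99).

## Quantification

Per islet: voxel count; physical volume `voxel_count · voxel_size³`;
axis-aligned bounding-box extents in µm; the mean 3D diameter
`(extent_x + extent_y + extent_z)/3` — the arithmetic-mean reading of the
"average length of x, y and z per islet" statistic (Feret/principal-axis
lengths are a noted alternative, not the default); unweighted centroid; and
intensity sum, mean and max over member voxels (validated against a
brute-force voxel loop). Size categories are half-open `[lo, hi)` — a value
exactly on an interior edge goes up — with 25-µm bins over 0–400 µm by
default; both count fractions and volume-weighted ("islet mass") fractions
are emitted because either reading of a mass distribution is defensible.
The orchestrated pipeline extends the grid upward in whole bin widths if an
unusually large islet exceeds the configured maximum; the core binning
operation keeps its strict out-of-range error. Reference comparison takes a
user-supplied CSV (`category_lo_um, category_hi_um, fraction`), e.g. from
published stereology; the package ships no reference numbers. Exports are
CSV (open format, bit-stable diffs) at full float precision; re-reading
with pandas' round-trip parser reproduces every value exactly.

## Orchestration and provenance

The pipeline fans a single global seed out to per-stage seeds via
`numpy.random.SeedSequence`, writes its effective config beside the outputs,
and records per stage a provenance JSON (parameter hash, input hashes,
output hashes, version, timestamp, wall time). A stage re-runs when its
outputs are missing or an upstream stage re-ran; identical (inputs, params,
seed) reproduce bit-identical outputs. TIFF (+ YAML sidecar) is the only
volume/stack format; uint16 stacks round-trip losslessly, float data is
written as float32 or scaled to uint16 with the scale recorded.

## Problem sizes used in validation

The end-to-end recovery experiment runs the full standard conditions
(192³ voxels, 500 islets, 400 projections) in ≈5 minutes on one CPU; the
remaining experiments use 64³–128³ phantoms with proportionally fewer
objects and angles, chosen so each isolates one stage at a scale where its
expected behavior is unambiguous. The unit and property tests run on
constructed arrays and 24³–128³ phantoms.

## Known limitations

* Recovery results certify the chain under the parallel-beam, PSF-free
  forward model; real OPT data adds optics and scanner corrections that are
  explicitly out of scope.
* Vertical drift and axis tilt are not estimated or corrected.
* The delineation separates dark regions by intensity and shape only; a
  tumor wrapped around a vessel, or one below ~1% of specimen volume, will
  be missed or truncated.
* Bounding-box extents overestimate the diameter of non-axis-aligned
  elongated islets; for spheres (the phantom's islets) the bias is below a
  voxel.
* Absolute reconstructed gray values depend on the preprocessing variant;
  comparisons across runs are structural unless the same variant was used.
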