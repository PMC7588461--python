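"""Ground-truthed synthetic autofluorescence pancreas phantoms and their
simulated OPT acquisition.

The phantom emulates the appearance of a cleared pancreas biopsy imaged by
near-infrared autofluorescence: a bright parenchyma blob containing

* droplet-like, high-AF spherical *islets* with lognormally distributed
  diameters,
* straight tubular vessel/duct-like structures of lower AF, and
* optionally an embedded low-AF ellipsoidal *tumor* region, strictly darker
  than the surrounding parenchyma,

plus the acquisition artifacts a real scan suffers from: a center-of-rotation
offset, photon/readout noise and a smooth uneven-illumination baseline.

The forward model is a parallel-beam line integral: each frame is the sum of
the volume along the optical axis after rotating the volume about the vertical
(z) axis by the frame angle, then shifting horizontally by the
center-of-rotation offset. Telecentric OPT optics are conventionally
approximated this way, which makes filtered back-projection the exact inverse
in the noiseless dense-angle limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ProjectionStack, Volume

__all__ = [
    "PhantomSpec",
    "TumorEllipsoid",
    "GroundTruth",
    "AcquisitionSpec",
    "PhantomPlacementError",
    "generate_phantom",
    "forward_project",
    "match_to_ground_truth",
]

# ground-truth label semantics
LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_TUMOR = 2
LABEL_VESSEL = 3
LABEL_FIRST_ISLET = 4


class PhantomPlacementError(RuntimeError):
    """Raised when islets cannot be placed without overlap in the attempt budget."""


@dataclass
class TumorEllipsoid:
    """Low-AF ellipsoidal region embedded in the parenchyma.

    ``intensity_factor`` multiplies the parenchyma intensity and must lie in
    [0, 1) so the tumor is strictly darker than normal tissue.
    """

    center_vox: tuple[float, float, float]  # (z, y, x)
    semi_axes_vox: tuple[float, float, float]
    intensity_factor: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity_factor < 1.0):
            raise ValueError(
                f"tumor intensity_factor must be in [0, 1), got {self.intensity_factor}"
            )
        if any(a <= 0 for a in self.semi_axes_vox):
            raise ValueError("tumor semi-axes must be positive")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic pancreas volume.

    Defaults are the standard study conditions used throughout the test
    phantoms: a 192^3 grid at 10 um voxels holding 500 islets with diameters
    lognormal(mu=ln 100 um, sigma=0.4) at 3:1 islet:parenchyma contrast.
    """

    shape_vox: tuple[int, int, int] = (192, 192, 192)  # (z, y, x)
    voxel_size_um: float = 10.0
    n_islets: int = 500
    islet_diameter_log_mu: float = math.log(100.0)  # log um
    islet_diameter_log_sigma: float = 0.4
    islet_intensity: float = 3.0
    parenchyma_intensity: float = 1.0
    tumor_ellipsoid: TumorEllipsoid | None = None
    n_vessels: int = 4
    vessel_radius_um: float = 30.0
    vessel_intensity: float = 0.5
    baseline_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape_vox) != 3 or any(int(s) <= 0 for s in self.shape_vox):
            raise ValueError(f"shape_vox must be 3 positive ints, got {self.shape_vox}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.n_islets < 0 or self.n_vessels < 0:
            raise ValueError("object counts must be non-negative")
        if self.islet_diameter_log_sigma < 0:
            raise ValueError("islet_diameter_log_sigma must be non-negative")
        if min(self.islet_intensity, self.parenchyma_intensity, self.vessel_intensity) <= 0:
            raise ValueError("intensities must be positive")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be non-negative")


@dataclass
class GroundTruth:
    """Per-voxel labels and the per-islet truth table of a phantom.

    ``label_volume``: 0 background, 1 parenchyma, 2 tumor, 3 vessel, >=4 one
    label per islet. ``islet_table`` columns: id, cz, cy, cx (voxel
    coordinates), diameter_um, volume_um3 with volume = (pi/6) d^3.
    """

    label_volume: np.ndarray
    islet_table: pd.DataFrame
    voxel_size_um: float = 10.0

    def islet_label_ids(self) -> np.ndarray:
        return self.islet_table["id"].to_numpy()


@dataclass
class AcquisitionSpec:
    """Simulated OPT scan geometry and noise.

    ``noise_scale`` is the Gaussian sigma expressed as a fraction of the
    parenchyma intensity (for ``poisson_gaussian`` it additionally sets the
    relative photon-noise level at the brightest ray).
    """

    n_angles: int = 400
    angular_range_deg: float = 360.0
    cor_offset_px: float = 0.0
    noise_model: Literal["none", "gaussian", "poisson_gaussian"] = "poisson_gaussian"
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if self.angular_range_deg <= 0:
            raise ValueError("angular_range_deg must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.noise_model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def angles_deg(self) -> np.ndarray:
        return np.linspace(0.0, self.angular_range_deg, self.n_angles, endpoint=False)


# ---------------------------------------------------------------------------
# phantom construction


def _tissue_ellipsoid(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Biopsy-shaped tissue mask: an ellipsoid comfortably inside the
    inscribed cylinder so rotation never clips tissue.

    Returns (mask, center, semi_axes) with center/semi_axes in (z, y, x).
    """
    shape_a = np.asarray(shape, dtype=float)
    center = (shape_a - 1) / 2.0
    # slightly unequal semi-axes: elongated along z, flattened in x; the
    # transverse semi-axes stay below half-width so rotation never clips tissue
    semi = shape_a * np.array([0.47, 0.455, 0.425])
    zz, yy, xx = np.indices(shape)
    q = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    return q <= 1.0, center, semi


def _paint_ball(volume: np.ndarray, labels: np.ndarray, center: np.ndarray,
                radius: float, value: float, label: int) -> None:
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2).astype(int), volume.shape)
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius ** 2
    sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    volume[sub][inside] = value
    labels[sub][inside] = label


def _inside_reduced_ellipsoid(p: np.ndarray, center: np.ndarray, semi: np.ndarray,
                              margin: float) -> bool:
    """True when a ball of radius ``margin`` centered at p fits in the ellipsoid."""
    s = semi - margin
    if np.any(s <= 0):
        return False
    return float(np.sum(((p - center) / s) ** 2)) <= 1.0


def _point_segment_distance(p: np.ndarray, a: np.ndarray, u: np.ndarray,
                            t0: float, t1: float) -> float:
    """Distance from point p to the segment a + t*u, t in [t0, t1]."""
    t = float(np.clip(np.dot(p - a, u), t0, t1))
    return float(np.linalg.norm(p - (a + t * u)))


def _line_ellipsoid_chord(a: np.ndarray, u: np.ndarray, center: np.ndarray,
                          semi: np.ndarray) -> tuple[float, float]:
    """Parameter range of the chord the line a + t*u cuts through the ellipsoid."""
    d = (a - center) / semi
    v = u / semi
    qa = float(np.dot(v, v))
    qb = 2.0 * float(np.dot(d, v))
    qc = float(np.dot(d, d)) - 1.0
    disc = qb * qb - 4 * qa * qc
    if disc <= 0:
        return 0.0, 0.0
    s = math.sqrt(disc)
    return (-qb - s) / (2 * qa), (-qb + s) / (2 * qa)


def _chord_hits_ellipsoid(a: np.ndarray, u: np.ndarray, t_center: np.ndarray,
                          t_semi: np.ndarray, e_center: np.ndarray,
                          e_semi: np.ndarray, n_samples: int = 100) -> bool:
    """True if the chord of line (a, u) through the tissue passes inside the
    (inflated) ellipsoid (e_center, e_semi)."""
    t0, t1 = _line_ellipsoid_chord(a, u, t_center, t_semi)
    if t1 <= t0:
        return False
    ts = np.linspace(t0, t1, n_samples)
    pts = a[None, :] + ts[:, None] * u[None, :]
    q = np.sum(((pts - e_center) / e_semi) ** 2, axis=1)
    return bool(np.any(q <= 1.0))


def _smooth_baseline_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth field in [-1, 1] modelling uneven illumination / depth falloff."""
    zz, yy, xx = [np.linspace(-1.0, 1.0, s) for s in shape]
    g = rng.normal(size=3)
    g /= np.linalg.norm(g) + 1e-12
    phase = rng.uniform(0, 2 * np.pi)
    field = (
        g[0] * zz[:, None, None]
        + g[1] * yy[None, :, None]
        + g[2] * xx[None, None, :]
        + 0.5 * np.sin(np.pi * xx[None, None, :] + phase)
    )
    m = np.abs(field).max()
    return field / m if m > 0 else field


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Build a seeded synthetic AF pancreas volume plus its ground truth.

    Placement uses rejection sampling: islet centers must keep the whole
    sphere inside the tissue ellipsoid, clear of the tumor and vessels, and a
    >=1-voxel gap from every other islet (so distinct islets never merge under
    26-connectivity). Identical specs (including seed) produce bit-identical
    output.

    Raises
    ------
    PhantomPlacementError
        If placement fails within ``10 * n_islets`` additional rejection
        attempts beyond the one nominal attempt per islet.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape_vox)
    vs = spec.voxel_size_um

    tissue, t_center, t_semi = _tissue_ellipsoid(shape)
    volume = np.zeros(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint16)
    volume[tissue] = spec.parenchyma_intensity
    labels[tissue] = LABEL_PARENCHYMA

    # tumor: darker ellipsoidal inclusion
    tumor = spec.tumor_ellipsoid
    if tumor is not None:
        tc = np.asarray(tumor.center_vox, dtype=float)
        ts = np.asarray(tumor.semi_axes_vox, dtype=float)
        zz, yy, xx = np.indices(shape)
        q = (
            ((zz - tc[0]) / ts[0]) ** 2
            + ((yy - tc[1]) / ts[1]) ** 2
            + ((xx - tc[2]) / ts[2]) ** 2
        )
        inside = (q <= 1.0) & tissue
        volume[inside] = spec.parenchyma_intensity * tumor.intensity_factor
        labels[inside] = LABEL_TUMOR

    # vessels: straight cylinders of random orientation clipped to tissue
    vessel_lines: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    vessel_r = spec.vessel_radius_um / vs
    if spec.n_vessels > 0:
        zz, yy, xx = np.indices(shape)
        pts = np.stack([zz, yy, xx], axis=-1).astype(np.float32)
        for _ in range(spec.n_vessels):
            for _attempt in range(100):
                a = t_center + (rng.uniform(-0.5, 0.5, 3) * t_semi)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                if not _inside_reduced_ellipsoid(a, t_center, t_semi, vessel_r + 1):
                    continue
                if tumor is not None and _chord_hits_ellipsoid(
                    a, u, t_center, t_semi,
                    np.asarray(tumor.center_vox, float),
                    np.asarray(tumor.semi_axes_vox, float) + vessel_r + 2.0,
                ):
                    # vessels steer clear of the tumor so each ground-truth
                    # voxel has a single unambiguous label
                    continue
                break
            d = pts - a.astype(np.float32)
            proj = d @ u.astype(np.float32)
            perp2 = np.einsum("zyxi,zyxi->zyx", d, d) - proj ** 2
            inside = (perp2 <= vessel_r ** 2) & tissue
            volume[inside] = spec.vessel_intensity
            labels[inside] = LABEL_VESSEL
            t0, t1 = _line_ellipsoid_chord(a, u, t_center, t_semi)
            vessel_lines.append((a, u, t0, t1))

    # islets: lognormal diameters, non-overlapping rejection sampling;
    # placing large islets first eases packing without biasing the sample
    diam_um = rng.lognormal(spec.islet_diameter_log_mu, spec.islet_diameter_log_sigma,
                            size=spec.n_islets)
    diam_um = np.sort(diam_um)[::-1]
    centers = np.empty((spec.n_islets, 3))
    radii_vox = diam_um / (2.0 * vs)
    max_extra = 10 * spec.n_islets
    extra_used = 0
    placed = 0
    gap_vox = 2.0
    while placed < spec.n_islets:
        r = radii_vox[placed]
        reduced = t_semi - (r + 1.0)
        if np.any(reduced <= 0):
            raise PhantomPlacementError(
                f"islet diameter {diam_um[placed]:.1f} um does not fit inside the "
                f"tissue ellipsoid of semi-axes {t_semi * vs} um"
            )
        # uniform sample inside the reduced ellipsoid: the whole sphere then
        # fits inside the tissue by construction
        u = rng.normal(size=3)
        u /= np.linalg.norm(u) + 1e-12
        p = t_center + u * reduced * rng.uniform() ** (1.0 / 3.0)
        ok = True
        if tumor is not None:
            # 1-voxel clearance: islets merging with the (dark) tumor or
            # vessels is not a segmentation hazard, unlike islet-islet fusion
            ts = np.asarray(tumor.semi_axes_vox, dtype=float) + r + 1.0
            tc = np.asarray(tumor.center_vox, dtype=float)
            ok = float(np.sum(((p - tc) / ts) ** 2)) > 1.0
        if ok:
            for a, u, t0, t1 in vessel_lines:
                if _point_segment_distance(p, a, u, t0, t1) <= r + vessel_r + 1.0:
                    ok = False
                    break
        if ok and placed > 0:
            d2 = np.sum((centers[:placed] - p) ** 2, axis=1)
            min_sep = radii_vox[:placed] + r + gap_vox
            ok = bool(np.all(d2 > min_sep ** 2))
        if ok:
            centers[placed] = p
            placed += 1
        else:
            extra_used += 1
            if extra_used > max_extra:
                raise PhantomPlacementError(
                    f"could not place islet {placed + 1}/{spec.n_islets} after "
                    f"{max_extra} rejection attempts: shape={shape}, "
                    f"mean diameter {float(np.mean(diam_um)):.1f} um at "
                    f"voxel {vs} um — reduce n_islets or diameters, or enlarge the volume"
                )

    for i in range(spec.n_islets):
        _paint_ball(volume, labels, centers[i], radii_vox[i],
                    spec.islet_intensity, LABEL_FIRST_ISLET + i)

    # uneven illumination: smooth multiplicative modulation of the whole tissue
    if spec.baseline_amplitude > 0:
        fld = _smooth_baseline_field(shape, rng)
        volume *= (1.0 + spec.baseline_amplitude * fld).astype(np.float32)

    table = pd.DataFrame(
        {
            "id": np.arange(LABEL_FIRST_ISLET, LABEL_FIRST_ISLET + spec.n_islets),
            "cz": centers[:, 0],
            "cy": centers[:, 1],
            "cx": centers[:, 2],
            "diameter_um": diam_um,
            "volume_um3": (np.pi / 6.0) * diam_um ** 3,
        }
    )
    vol = Volume(
        volume,
        voxel_size_um=vs,
        meta={"phantom_seed": spec.seed,
              "parenchyma_intensity": spec.parenchyma_intensity},
    )
    return vol, GroundTruth(label_volume=labels, islet_table=table, voxel_size_um=vs)


# ---------------------------------------------------------------------------
# forward projection


def _rotate_about_z(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate every z-slice in the (y, x) plane about the sub-pixel center.

    Linear interpolation, zero fill outside the field of view. The sign
    convention matches the classical Radon transform: a point at (dy, dx)
    from the center projects to detector coordinate dx*cos(t) - dy*sin(t).
    """
    a = np.deg2rad(angle_deg)
    cos_a, sin_a = np.cos(a), np.sin(a)
    # snap near-exact values so cardinal rotations map grid points to grid
    # points instead of epsilon-outside-the-array coordinates
    cos_a = round(cos_a) if abs(cos_a - round(cos_a)) < 1e-12 else cos_a
    sin_a = round(sin_a) if abs(sin_a - round(sin_a)) < 1e-12 else sin_a
    rot2 = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
    matrix = np.eye(3)
    matrix[1:, 1:] = rot2
    c = (np.asarray(data.shape, dtype=float) - 1) / 2.0
    offset = c - matrix @ c
    return ndimage.affine_transform(data, matrix, offset=offset, order=1,
                                    prefilter=False, mode="constant", cval=0.0)


def _fourier_shift_x(frame: np.ndarray, shift_px: float) -> np.ndarray:
    """Sub-pixel horizontal shift by Fourier phase ramp (exact, periodic)."""
    if shift_px == 0.0:
        return frame
    f = np.fft.rfft(frame, axis=-1)
    freqs = np.fft.rfftfreq(frame.shape[-1])
    f *= np.exp(-2j * np.pi * freqs * shift_px)
    return np.fft.irfft(f, n=frame.shape[-1], axis=-1).astype(frame.dtype, copy=False)


def forward_project(volume: Volume, acq: AcquisitionSpec) -> ProjectionStack:
    """Simulate the OPT scan of a volume: parallel-beam line integrals.

    Frame values are discrete line integrals in voxel units (plain sums along
    the optical axis after rotation), shifted horizontally by
    ``acq.cor_offset_px`` and degraded per the noise model.
    """
    if not volume.is_isotropic:
        raise ValueError(
            f"parallel-beam projection assumes isotropic voxels, got {volume.voxel_size_um}"
        )
    angles = acq.angles_deg()
    data = np.ascontiguousarray(volume.data, dtype=np.float32)
    frames = np.empty((acq.n_angles, data.shape[0], data.shape[2]), dtype=np.float32)
    for k, th in enumerate(angles):
        frames[k] = _rotate_about_z(data, th).sum(axis=1)
    if acq.cor_offset_px != 0.0:
        frames = _fourier_shift_x(frames, acq.cor_offset_px)

    if acq.noise_model != "none" and acq.noise_scale > 0:
        rng = np.random.default_rng(acq.seed)
        # sigma referenced to the parenchyma voxel intensity, if known
        ref = float(volume.meta.get("parenchyma_intensity", 1.0))
        sigma = acq.noise_scale * ref
        if acq.noise_model == "poisson_gaussian":
            peak = float(frames.max())
            if peak > 0:
                n_photons = 1.0 / acq.noise_scale ** 2  # relative shot noise at peak
                lam = np.clip(frames, 0, None) * (n_photons / peak)
                frames = rng.poisson(lam).astype(np.float32) * (peak / n_photons)
        frames = frames + rng.normal(0.0, sigma, size=frames.shape).astype(np.float32)

    return ProjectionStack(
        frames=frames,
        angles_deg=angles,
        pixel_size_um=volume.voxel_size_scalar_um,
        cor_offset_px=acq.cor_offset_px,
        meta={"noise_model": acq.noise_model, "noise_scale": acq.noise_scale,
              "acq_seed": acq.seed},
    )


# ---------------------------------------------------------------------------
# validation oracle


def match_to_ground_truth(
    measured_centroids_vox: np.ndarray,
    truth: GroundTruth,
    max_dist_vox: float = 3.0,
) -> np.ndarray:
    """Greedily match measured object centroids to true islet centers.

    Returns an integer array of the same length as ``measured_centroids_vox``:
    the row index into ``truth.islet_table`` of the matched islet, or -1 for
    unmatched (spurious) objects. Each true islet is used at most once;
    candidate pairs are taken in order of increasing distance.
    """
    meas = np.asarray(measured_centroids_vox, dtype=float)
    true_c = truth.islet_table[["cz", "cy", "cx"]].to_numpy()
    if meas.size == 0 or true_c.size == 0:
        return np.full(len(meas), -1, dtype=int)
    d = np.linalg.norm(meas[:, None, :] - true_c[None, :, :], axis=2)
    assign = np.full(len(meas), -1, dtype=int)
    used = np.zeros(len(true_c), dtype=bool)
    pairs = np.argwhere(d <= max_dist_vox)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    taken = np.zeros(len(meas), dtype=bool)
    for i, j in pairs[order]:
        if not taken[i] and not used[j]:
            assign[i] = j
            taken[i] = True
            used[j] = True
    return assign
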