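"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
* Volumes are indexed ``(z, y, x)`` with 0-based voxel indices; the tomographic
  rotation axis is ``z`` (the vertical/longitudinal specimen axis).
* Projection frames are indexed ``(row, column) == (z, x)``: detector rows map
  one-to-one onto reconstructed z-sections.
* Sub-pixel centers use the ``(n - 1) / 2`` convention, so flipping an array
  mirrors it exactly about the rotation center for any width parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ProjectionStack", "Volume", "Sinogram", "center_px"]


def center_px(n: int) -> float:
    """Sub-pixel center of an axis with ``n`` samples."""
    return (n - 1) / 2.0


@dataclass
class ProjectionStack:
    """Angle-indexed stack of 2D projection frames plus acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_angles, height, width)
        One grayscale frame per rotation angle.
    angles_deg : ndarray, shape (n_angles,)
        Rotation-stage angle of each frame, degrees.
    pixel_size_um : float
        Detector pixel pitch at the specimen, micrometres.
    cor_offset_px : float or None
        Known signed horizontal offset of the rotation axis from the detector
        center column, pixels. ``None`` when unknown (real acquisitions).
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    pixel_size_um: float
    cor_offset_px: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n_angles, H, W), got shape {self.frames.shape}")
        if self.angles_deg.shape != (self.frames.shape[0],):
            raise ValueError(
                f"{self.frames.shape[0]} frames but {self.angles_deg.size} angles"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_angles(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    def angular_spacing_deg(self) -> float:
        d = np.diff(np.sort(self.angles_deg))
        return float(np.median(d)) if d.size else 0.0

    def replace_frames(self, frames: np.ndarray, **meta: Any) -> "ProjectionStack":
        """New stack with identical geometry but different pixel data."""
        new_meta = {**self.meta, **meta}
        return ProjectionStack(
            frames=frames,
            angles_deg=self.angles_deg.copy(),
            pixel_size_um=self.pixel_size_um,
            cor_offset_px=self.cor_offset_px,
            meta=new_meta,
        )


@dataclass
class Volume:
    """Isotropic 3D voxel grid with a physical voxel size.

    ``voxel_size_um`` may be a scalar (isotropic, the normal case) or a
    3-tuple; anisotropic volumes are accepted as containers but rejected by
    stages whose physics assumes isotropy (the parallel-beam projector).
    """

    data: np.ndarray
    voxel_size_um: float | tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D (z, y, x), got shape {self.data.shape}")
        vs = np.atleast_1d(np.asarray(self.voxel_size_um, dtype=float))
        if np.any(vs <= 0):
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        vs = np.atleast_1d(np.asarray(self.voxel_size_um, dtype=float))
        return bool(np.all(vs == vs.flat[0]))

    @property
    def voxel_size_scalar_um(self) -> float:
        if not self.is_isotropic:
            raise ValueError(f"volume is anisotropic: voxel_size_um={self.voxel_size_um}")
        return float(np.atleast_1d(np.asarray(self.voxel_size_um, dtype=float))[0])

    @property
    def voxel_volume_um3(self) -> float:
        vs = np.atleast_1d(np.asarray(self.voxel_size_um, dtype=float))
        return float(np.prod(vs)) if vs.size == 3 else float(vs[0] ** 3)


@dataclass
class Sinogram:
    """All projections of one detector row: shape ``(n_angles, width)``."""

    data: np.ndarray
    angles_deg: np.ndarray
    pixel_size_um: float
    row: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"sinogram must be 2D (n_angles, W), got {self.data.shape}")
        if self.angles_deg.shape != (self.data.shape[0],):
            raise ValueError("one angle per sinogram row required")
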