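"""Projection-domain conditioning: percentile range cutting and CLAHE.

Range cutting clips the stack to global intensity percentiles and rescales to
[0, 1], boosting signal-to-background ratio; being affine on the non-clipped
range it is safe for quantitative work. CLAHE (contrast-limited adaptive
histogram equalization, 32x32-pixel tiles by default) improves local contrast
for visualization and registration but is non-linear, so reconstructions
intended for intensity quantification are normally computed from range-cut
frames only (``clahe_enabled=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .core import ProjectionStack

__all__ = ["PreprocessParams", "cut_range", "clahe"]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    clip_lo_percentile: float = 1.0
    clip_hi_percentile: float = 99.5
    clahe_tile: tuple[int, int] = (32, 32)
    clahe_clip_limit: float = 0.01  # fraction-of-tile-pixels convention
    clahe_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.clip_lo_percentile < 100.0):
            raise ValueError("clip_lo_percentile must be in [0, 100)")
        if not (self.clip_lo_percentile < self.clip_hi_percentile <= 100.0):
            raise ValueError("clip_hi_percentile must be in (clip_lo, 100]")
        if any(int(t) <= 0 for t in self.clahe_tile):
            raise ValueError("clahe_tile dimensions must be positive")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")


def cut_range(stack: ProjectionStack, params: PreprocessParams | None = None) -> ProjectionStack:
    """Clip the stack to global percentiles and rescale linearly to [0, 1].

    Percentiles are computed over the whole stack (all frames jointly) so the
    mapping is identical for every angle. A constant stack (degenerate
    percentiles) yields an all-zeros stack with a logged warning rather than
    an error.
    """
    params = params or PreprocessParams()
    if stack.frames.size == 0:
        raise ValueError("empty projection stack")
    data = stack.frames.astype(np.float32, copy=False)
    p_lo, p_hi = np.percentile(data, [params.clip_lo_percentile, params.clip_hi_percentile])
    if p_hi == p_lo:
        logger.warning(
            "range cut degenerate: percentile %.4g == %.4g; returning all-zero stack",
            params.clip_lo_percentile, params.clip_hi_percentile,
        )
        return stack.replace_frames(np.zeros_like(data), range_cut=(float(p_lo), float(p_hi)))
    out = np.clip(data, p_lo, p_hi)
    out = (out - p_lo) / (p_hi - p_lo)
    return stack.replace_frames(out.astype(np.float32),
                                range_cut=(float(p_lo), float(p_hi)))


def clahe(stack: ProjectionStack, params: PreprocessParams | None = None) -> ProjectionStack:
    """Per-frame contrast-limited adaptive histogram equalization.

    Each frame is partitioned into the tile grid, per-tile histograms (256
    bins) are clipped at ``clahe_clip_limit`` with the excess redistributed,
    and the per-tile equalization mappings are bilinearly interpolated between
    tile centers. Frames must already be scaled to [0, 1] (run
    :func:`cut_range` first); output stays in [0, 1].
    """
    params = params or PreprocessParams()
    frames = stack.frames
    tile = tuple(int(t) for t in params.clahe_tile)
    h, w = stack.frame_shape
    if tile[0] > h or tile[1] > w:
        raise ValueError(f"CLAHE tile {tile} larger than frame ({h}, {w})")
    if frames.min() < 0 or frames.max() > 1:
        raise ValueError("clahe expects frames in [0, 1]; apply cut_range first")
    out = np.empty_like(frames, dtype=np.float32)
    for k in range(frames.shape[0]):
        frame = frames[k]
        if np.ptp(frame) == 0:
            out[k] = frame  # constant frame: equalization is the identity
            continue
        out[k] = exposure.equalize_adapthist(
            frame.astype(np.float64), kernel_size=tile,
            clip_limit=params.clahe_clip_limit, nbins=256,
        )
    return stack.replace_frames(out, clahe={"tile": tile, "clip_limit": params.clahe_clip_limit})
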