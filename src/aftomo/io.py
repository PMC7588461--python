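"""File I/O: multi-page TIFF stacks/volumes with YAML metadata sidecars.

Every array on disk is a grayscale multi-page TIFF (one page per angle for
projection stacks, one page per z-section for volumes) accompanied by a YAML
sidecar of the same stem carrying the physical metadata (angles, pixel size,
known center-of-rotation offset, seeds, and the linear scale used when float
data was packed into 16-bit).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import ProjectionStack, Volume
from .segment import LabelVolume

__all__ = [
    "write_projection_stack", "read_projection_stack",
    "write_volume", "read_volume",
    "write_labels", "read_labels",
    "write_mask", "read_mask",
]

logger = logging.getLogger(__name__)

STACK_SIDECAR_KEYS = ("angles_deg", "pixel_size_um")


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def _dump_yaml(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _load_yaml(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_projection_stack(stack: ProjectionStack, path: str | Path,
                           dtype: str = "uint16") -> Path:
    """Write frames as a multi-page TIFF plus a YAML sidecar.

    Float frames are linearly scaled to the full uint16 range with the scale
    recorded in the sidecar (``uint16 -> float`` round trips exactly up to
    that quantization; uint16 input round-trips bit-identically with
    ``dtype='uint16'``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = stack.frames
    meta: dict = {
        "angles_deg": [float(a) for a in stack.angles_deg],
        "pixel_size_um": float(stack.pixel_size_um),
    }
    if stack.cor_offset_px is not None:
        meta["cor_offset_px"] = float(stack.cor_offset_px)
    for key in ("phantom_seed", "acq_seed", "noise_model", "noise_scale"):
        if key in stack.meta:
            meta[key] = stack.meta[key]
    if dtype == "uint16" and frames.dtype != np.uint16:
        lo, hi = float(frames.min()), float(frames.max())
        scale = (hi - lo) or 1.0
        packed = np.round((frames - lo) / scale * 65535.0).astype(np.uint16)
        meta["value_scale"] = {"lo": lo, "hi": hi}
        tifffile.imwrite(path, packed, photometric="minisblack")
    elif dtype == "float32":
        tifffile.imwrite(path, frames.astype(np.float32), photometric="minisblack")
    else:
        tifffile.imwrite(path, frames, photometric="minisblack")
    _dump_yaml(_sidecar_path(path), meta)
    return path


def read_projection_stack(path: str | Path) -> ProjectionStack:
    """Read a multi-page grayscale TIFF stack and its YAML sidecar.

    Errors name unsupported variants (RGB pages) and missing sidecar keys; a
    page count disagreeing with the sidecar's angle list is rejected.
    Non-uniform angle spacing is accepted with a logged warning.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar}; required keys: "
            f"{', '.join(STACK_SIDECAR_KEYS)}"
        )
    meta = _load_yaml(sidecar)
    missing = [k for k in STACK_SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sidecar} missing required keys: {missing}")
    with tifffile.TiffFile(path) as tf:
        photometric = tf.pages[0].photometric
        samples = tf.pages[0].samplesperpixel
        if samples != 1 or photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK, tifffile.PHOTOMETRIC.MINISWHITE
        ):
            raise ValueError(
                f"{path}: TIFF variant not supported "
                f"(photometric={photometric.name}, {samples} samples/pixel); "
                f"expected multi-page grayscale"
            )
        frames = tf.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected multi-page grayscale TIFF, got shape {frames.shape}"
        )
    angles = np.asarray(meta["angles_deg"], dtype=float)
    if angles.size != frames.shape[0]:
        raise ValueError(
            f"{path}: {frames.shape[0]} TIFF pages but {angles.size} sidecar angles"
        )
    d = np.diff(angles)
    if d.size and np.any(np.abs(d - d[0]) > 1e-6):
        logger.warning("%s: sidecar angles are not uniformly spaced; downstream "
                       "stages widen their angular tolerance", path)
    if "value_scale" in meta:
        lo, hi = meta["value_scale"]["lo"], meta["value_scale"]["hi"]
        frames = frames.astype(np.float32) / 65535.0 * (hi - lo) + lo
    extra = {k: v for k, v in meta.items()
             if k not in ("angles_deg", "pixel_size_um", "cor_offset_px")}
    return ProjectionStack(
        frames=frames,
        angles_deg=angles,
        pixel_size_um=float(meta["pixel_size_um"]),
        cor_offset_px=meta.get("cor_offset_px"),
        meta=extra,
    )


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as float32 multi-page TIFF (one page per z-section)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(volume.data)
    if data.dtype not in (np.uint8, np.uint16):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"voxel_size_um": float(volume.voxel_size_scalar_um)}
    meta.update({k: v for k, v in volume.meta.items()
                 if isinstance(v, (int, float, str, bool, list))})
    _dump_yaml(_sidecar_path(path), meta)
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}; "
                                f"required key: voxel_size_um")
    meta = _load_yaml(sidecar)
    if "voxel_size_um" not in meta:
        raise KeyError(f"sidecar {sidecar} missing required key voxel_size_um")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    vs = meta.pop("voxel_size_um")
    return Volume(data, voxel_size_um=float(vs), meta=meta)


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """16-bit labeled TIFF (errors if more than 65535 objects)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError(f"{labels.labels.max()} labels exceed the uint16 range")
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")
    _dump_yaml(_sidecar_path(path), {
        "voxel_size_um": float(labels.voxel_size_um),
        "provenance": _jsonable(labels.provenance),
    })
    return path


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    meta = _load_yaml(_sidecar_path(path))
    return LabelVolume(tifffile.imread(path).astype(np.int32),
                       voxel_size_um=float(meta["voxel_size_um"]),
                       provenance=meta.get("provenance") or {})


def write_mask(mask: np.ndarray, voxel_size_um: float, path: str | Path) -> Path:
    """Binary mask as 8-bit TIFF (255 = inside)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255,
                     photometric="minisblack")
    _dump_yaml(_sidecar_path(path), {"voxel_size_um": float(voxel_size_um)})
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
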