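"""Per-islet statistics, size-category distributions, and exports.

The central per-object statistic is the *mean 3D diameter*: the arithmetic
mean of the axis-aligned bounding-box extents in x, y and z. Islets are
binned by that diameter into size categories (default 25-um bins spanning
0-400 um), yielding both a count-fraction distribution and a volume-weighted
("islet mass") variant, and either can be compared numerically against a
user-supplied reference table from stereological assessments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Volume
from .segment import LabelVolume

__all__ = [
    "IsletRecord",
    "SizeDistribution",
    "ComparisonReport",
    "measure_islets",
    "per_object_intensity_stats",
    "mip",
    "size_distribution",
    "default_category_edges",
    "compare_to_reference",
    "export_statistics",
    "records_to_frame",
    "read_reference_distribution",
]

ISLET_CSV_COLUMNS = [
    "label_id", "voxel_count", "volume_um3",
    "extent_x_um", "extent_y_um", "extent_z_um", "mean_diameter_um",
    "centroid_z_vox", "centroid_y_vox", "centroid_x_vox", "intensity_sum",
]


@dataclass
class IsletRecord:
    """One segmented islet: geometry and intensity summary.

    ``mean_diameter_um`` is exactly ``(extent_x + extent_y + extent_z) / 3``;
    ``volume_um3`` is ``voxel_count * voxel_size**3``.
    """

    label_id: int
    voxel_count: int
    volume_um3: float
    extent_x_um: float
    extent_y_um: float
    extent_z_um: float
    mean_diameter_um: float
    centroid_vox: tuple[float, float, float]  # (z, y, x)
    intensity_sum: float


@dataclass
class SizeDistribution:
    """Counts, fractions and summed islet volume per diameter category.

    Binning is half-open ``[lo, hi)`` on the mean diameter: a value exactly on
    an interior edge falls in the upper bin. ``counts`` may be ``None`` for a
    fractions-only reference table (e.g., published stereology).
    """

    category_edges_um: np.ndarray
    fractions: np.ndarray
    counts: np.ndarray | None = None
    n_total: int = 0
    volume_um3: np.ndarray | None = None
    volume_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.category_edges_um = np.asarray(self.category_edges_um, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.category_edges_um) <= 0):
            raise ValueError("category edges must be strictly increasing")
        if self.fractions.size != self.category_edges_um.size - 1:
            raise ValueError("need one fraction per category")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if int(self.counts.sum()) != self.n_total:
                raise ValueError("sum of counts must equal n_total")
        if self.n_total > 0 and abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class ComparisonReport:
    """Numeric comparison of two size distributions over identical categories."""

    category_edges_um: np.ndarray
    fraction_diff: np.ndarray  # observed - reference, per category
    total_variation: float
    chi_square: float
    dof: int


def default_category_edges(max_um: float = 400.0, width_um: float = 25.0) -> np.ndarray:
    """Diameter category edges: ``width_um``-wide bins from 0 to ``max_um``."""
    return np.arange(0.0, max_um + width_um / 2, width_um)


def measure_islets(labels: LabelVolume, intensity: Volume) -> list[IsletRecord]:
    """One record per labeled object: bounding-box extents, mean diameter,
    voxel count, physical volume, centroid and intensity sum."""
    if labels.labels.shape != intensity.shape:
        raise ValueError(
            f"label volume {labels.labels.shape} and intensity volume "
            f"{intensity.shape} do not share geometry"
        )
    lab = labels.labels
    n = int(lab.max())
    if n == 0:
        return []
    vs = labels.voxel_size_um
    ids = np.arange(1, n + 1)
    counts = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    sums = ndimage.sum_labels(np.asarray(intensity.data, dtype=np.float64), lab, ids)
    centroids = ndimage.center_of_mass(np.ones_like(lab, dtype=np.float32), lab, ids)
    slices = ndimage.find_objects(lab)
    records = []
    for i, obj_id in enumerate(ids):
        sl = slices[obj_id - 1]
        ez, ey, ex = ((s.stop - s.start) * vs for s in sl)
        records.append(IsletRecord(
            label_id=int(obj_id),
            voxel_count=int(counts[i]),
            volume_um3=float(counts[i]) * vs ** 3,
            extent_x_um=float(ex),
            extent_y_um=float(ey),
            extent_z_um=float(ez),
            mean_diameter_um=float((ex + ey + ez) / 3.0),
            centroid_vox=tuple(float(c) for c in centroids[i]),
            intensity_sum=float(sums[i]),
        ))
    return records


def per_object_intensity_stats(labels: LabelVolume, intensity: Volume) -> pd.DataFrame:
    """Per-object sum, mean and max of intensity (columns: label_id,
    intensity_sum, intensity_mean, intensity_max)."""
    if labels.labels.shape != intensity.shape:
        raise ValueError("label and intensity volumes do not share geometry")
    lab = labels.labels
    n = int(lab.max())
    ids = np.arange(1, n + 1)
    data = np.asarray(intensity.data, dtype=np.float64)
    if n == 0:
        return pd.DataFrame(columns=["label_id", "intensity_sum", "intensity_mean",
                                     "intensity_max"])
    return pd.DataFrame({
        "label_id": ids,
        "intensity_sum": ndimage.sum_labels(data, lab, ids),
        "intensity_mean": ndimage.mean(data, lab, ids),
        "intensity_max": ndimage.maximum(data, lab, ids),
    })


_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


def mip(volume: Volume, axis: str = "y") -> np.ndarray:
    """Maximum intensity projection: elementwise max along one axis."""
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of {list(_AXIS_INDEX)}, got {axis!r}")
    data = np.asarray(volume.data)
    if data.size == 0:
        raise ValueError("empty volume")
    return data.max(axis=_AXIS_INDEX[axis])


def size_distribution(records: list[IsletRecord],
                      edges_um: np.ndarray | None = None) -> SizeDistribution:
    """Bin islets into diameter categories (half-open ``[lo, hi)``).

    Emits both count fractions and the per-category summed islet volume with
    its volume-weighted ("islet mass") fractions. A record whose mean
    diameter falls outside the edge range raises an error naming the
    offenders.
    """
    edges = np.asarray(default_category_edges() if edges_um is None else edges_um,
                       dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("category edges must be strictly increasing")
    if not records:
        raise ValueError("no islet records to bin")
    d = np.array([r.mean_diameter_um for r in records])
    vol = np.array([r.volume_um3 for r in records])
    outside = (d < edges[0]) | (d >= edges[-1])
    if outside.any():
        bad = sorted(float(x) for x in d[outside])
        raise ValueError(
            f"{outside.sum()} islet diameters outside category range "
            f"[{edges[0]}, {edges[-1]}): {bad[:10]}"
        )
    idx = np.digitize(d, edges) - 1  # [lo, hi): interior edge values go up
    n_cat = edges.size - 1
    counts = np.bincount(idx, minlength=n_cat)
    vols = np.bincount(idx, weights=vol, minlength=n_cat)
    n_total = int(counts.sum())
    return SizeDistribution(
        category_edges_um=edges,
        counts=counts,
        fractions=counts / n_total,
        n_total=n_total,
        volume_um3=vols,
        volume_fractions=vols / vols.sum() if vols.sum() > 0 else vols,
    )


def compare_to_reference(dist: SizeDistribution,
                         reference: SizeDistribution) -> ComparisonReport:
    """Numbers-only comparison: per-category fraction differences, total
    variation distance, and the chi-square statistic of the observed counts
    against the reference fractions (dof = n_categories - 1)."""
    if dist.category_edges_um.shape != reference.category_edges_um.shape or not np.allclose(
        dist.category_edges_um, reference.category_edges_um
    ):
        raise ValueError("distributions use different category edges")
    diff = dist.fractions - reference.fractions
    tv = 0.5 * float(np.abs(diff).sum())
    if dist.counts is None:
        raise ValueError("observed distribution needs counts for the chi-square")
    expected = reference.fractions * dist.n_total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0,
                         (dist.counts - expected) ** 2 / expected,
                         np.where(dist.counts > 0, np.inf, 0.0))
    return ComparisonReport(
        category_edges_um=dist.category_edges_um.copy(),
        fraction_diff=diff,
        total_variation=tv,
        chi_square=float(terms.sum()),
        dof=int(dist.fractions.size - 1),
    )


def records_to_frame(records: list[IsletRecord]) -> pd.DataFrame:
    rows = [
        {
            "label_id": r.label_id,
            "voxel_count": r.voxel_count,
            "volume_um3": r.volume_um3,
            "extent_x_um": r.extent_x_um,
            "extent_y_um": r.extent_y_um,
            "extent_z_um": r.extent_z_um,
            "mean_diameter_um": r.mean_diameter_um,
            "centroid_z_vox": r.centroid_vox[0],
            "centroid_y_vox": r.centroid_vox[1],
            "centroid_x_vox": r.centroid_vox[2],
            "intensity_sum": r.intensity_sum,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ISLET_CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[IsletRecord]:
    return [
        IsletRecord(
            label_id=int(row.label_id),
            voxel_count=int(row.voxel_count),
            volume_um3=float(row.volume_um3),
            extent_x_um=float(row.extent_x_um),
            extent_y_um=float(row.extent_y_um),
            extent_z_um=float(row.extent_z_um),
            mean_diameter_um=float(row.mean_diameter_um),
            centroid_vox=(float(row.centroid_z_vox), float(row.centroid_y_vox),
                          float(row.centroid_x_vox)),
            intensity_sum=float(row.intensity_sum),
        )
        for row in frame.itertuples()
    ]


def read_reference_distribution(path: str | Path) -> SizeDistribution:
    """Load a fractions-only reference table (columns: category_lo_um,
    category_hi_um, fraction), e.g., published stereological assessments."""
    tbl = pd.read_csv(path)
    required = {"category_lo_um", "category_hi_um", "fraction"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"reference CSV {path} must have columns {sorted(required)}")
    lo = tbl["category_lo_um"].to_numpy(dtype=float)
    hi = tbl["category_hi_um"].to_numpy(dtype=float)
    if not np.allclose(lo[1:], hi[:-1]):
        raise ValueError("reference categories must be contiguous")
    edges = np.concatenate([lo, hi[-1:]])
    return SizeDistribution(category_edges_um=edges,
                            fractions=tbl["fraction"].to_numpy(dtype=float))


def export_statistics(
    records: list[IsletRecord],
    dist: SizeDistribution | None,
    report: ComparisonReport | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write islets.csv, distribution.csv and comparison.csv (full float
    precision, bit-stable given identical inputs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    islets_path = out / "islets.csv"
    records_to_frame(records).to_csv(islets_path, index=False)
    paths["islets"] = islets_path
    if dist is not None:
        df = pd.DataFrame({
            "category_lo_um": dist.category_edges_um[:-1],
            "category_hi_um": dist.category_edges_um[1:],
            "count": dist.counts if dist.counts is not None else np.nan,
            "fraction": dist.fractions,
            "volume_um3": dist.volume_um3 if dist.volume_um3 is not None else np.nan,
            "volume_fraction": (dist.volume_fractions
                                if dist.volume_fractions is not None else np.nan),
        })
        dist_path = out / "distribution.csv"
        df.to_csv(dist_path, index=False)
        paths["distribution"] = dist_path
    if report is not None:
        df = pd.DataFrame({
            "category_lo_um": report.category_edges_um[:-1],
            "category_hi_um": report.category_edges_um[1:],
            "fraction_diff": report.fraction_diff,
        })
        df.attrs["total_variation"] = report.total_variation
        comp_path = out / "comparison.csv"
        with open(comp_path, "w") as fh:
            fh.write(f"# total_variation,{report.total_variation!r}\n")
            fh.write(f"# chi_square,{report.chi_square!r}\n")
            fh.write(f"# dof,{report.dof}\n")
            df.to_csv(fh, index=False)
        paths["comparison"] = comp_path
    return paths
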