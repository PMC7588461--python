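"""Pipeline orchestration: configuration, staged execution, caching, provenance.

A run directory holds one sub-directory per stage
(``simulate -> preprocess -> align -> reconstruct -> segment -> quantify``),
each with its outputs, a ``provenance.json`` (parameter hash, input hashes,
software version, timestamp, wall time) and, at the top level, the effective
configuration that produced the run. A stage is re-executed when its outputs
are missing or any upstream stage re-executed; deterministic stages reproduce
bit-identical outputs for identical (inputs, parameters, seed).

The single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence`` so stochastic stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .align import estimate_cor, apply_correction
from .io import (read_projection_stack, write_labels, write_mask,
                 write_projection_stack, write_volume, read_volume, read_labels,
                 _jsonable)
from .phantom import (AcquisitionSpec, PhantomSpec, TumorEllipsoid,
                      forward_project, generate_phantom)
from .preprocess import PreprocessParams, clahe, cut_range
from .quantify import (compare_to_reference, default_category_edges,
                       export_statistics, measure_islets,
                       read_reference_distribution, size_distribution)
from .reconstruct import ReconstructionParams, reconstruct_volume
from .segment import (SegmentationParams, delineate_low_af_region, label_islets,
                      remove_artifacts, subtract_baseline, tissue_mask)

__all__ = ["PipelineConfig", "QuantifyConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "align", "reconstruct", "segment", "quantify")


@dataclass
class QuantifyConfig:
    edges_max_um: float = 400.0
    edges_width_um: float = 25.0
    reference_csv: str | None = None
    tumor: bool = False  # also delineate the low-AF region


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run.

    ``input_stack`` switches the first stage from simulation to ingestion of
    an existing projection TIFF + sidecar. Per-stage seeds left at ``None``
    are derived from the global ``seed``.
    """

    seed: int = 0
    out_dir: str = "run"
    input_stack: str | None = None
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    reconstruct: ReconstructionParams = field(default_factory=ReconstructionParams)
    segment: SegmentationParams = field(default_factory=SegmentationParams)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


_BLOCK_TYPES = {
    "phantom": PhantomSpec,
    "acquisition": AcquisitionSpec,
    "preprocess": PreprocessParams,
    "reconstruct": ReconstructionParams,
    "segment": SegmentationParams,
    "quantify": QuantifyConfig,
}


def _build_block(cls, payload: dict, context: str):
    if payload is None:
        payload = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys in config block {context!r}: {sorted(unknown)}")
    kwargs = dict(payload)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and kwargs[f.name] is not None:
            if f.name == "tumor_ellipsoid" and isinstance(kwargs[f.name], dict):
                kwargs[f.name] = TumorEllipsoid(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[f.name].items()
                })
            elif isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Parse a YAML file (or pre-parsed mapping) into a PipelineConfig.

    Unknown keys anywhere are rejected (fail-fast) so typos cannot silently
    fall back to defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            payload = yaml.safe_load(fh) or {}
    else:
        payload = dict(source)
    top_scalars = {"seed", "out_dir", "input_stack"}
    unknown = set(payload) - top_scalars - set(_BLOCK_TYPES)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {k: payload[k] for k in top_scalars if k in payload}
    for name, cls in _BLOCK_TYPES.items():
        if name in payload:
            kwargs[name] = _build_block(cls, payload[name], name)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# provenance and caching


def _hash_bytes(*chunks: bytes) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c)
    return h.hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params) -> str:
    payload = json.dumps(_jsonable(dataclasses.asdict(params)) if
                         dataclasses.is_dataclass(params) else _jsonable(params),
                         sort_keys=True)
    return _hash_bytes(payload.encode())


class _StageRunner:
    """Runs stages in order, skipping those whose outputs are present and
    whose upstream stages did not re-execute."""

    def __init__(self, run_dir: Path):
        self.run_dir = run_dir
        self.upstream_dirty = False
        self.timings: dict[str, float] = {}

    def stage_dir(self, name: str) -> Path:
        return self.run_dir / name

    def is_cached(self, name: str, outputs: list[str]) -> bool:
        if self.upstream_dirty:
            return False
        d = self.stage_dir(name)
        if not (d / "provenance.json").exists():
            return False
        return all((d / o).exists() for o in outputs)

    def record(self, name: str, params_hash: str, input_hashes: dict[str, str],
               outputs: list[str], elapsed: float) -> None:
        d = self.stage_dir(name)
        prov = {
            "stage": name,
            "software_version": __version__,
            "params_hash": params_hash,
            "input_hashes": input_hashes,
            "output_hashes": {o: _hash_file(d / o) for o in outputs if (d / o).exists()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "wall_time_s": round(elapsed, 3),
        }
        with open(d / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
        self.timings[name] = elapsed
        logger.info("stage %-11s %7.2f s  params=%s", name, elapsed, params_hash[:12])


def _derive_seed(global_seed: int, stage_index: int) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory.

    Each stage is resumable: outputs already on disk are reused unless an
    upstream stage re-ran. A stage failure propagates with its stage name;
    outputs of completed stages are retained.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())
    runner = _StageRunner(run_dir)

    # --- simulate (or ingest)
    sim_dir = runner.stage_dir("simulate")
    stack_path = sim_dir / "projections.tif"
    if config.input_stack is not None:
        stack = read_projection_stack(config.input_stack)
        truth = None
    else:
        phantom_spec = dataclasses.replace(
            config.phantom,
            seed=config.phantom.seed if config.phantom.seed else _derive_seed(config.seed, 0),
        )
        acq_spec = dataclasses.replace(
            config.acquisition,
            seed=config.acquisition.seed if config.acquisition.seed
            else _derive_seed(config.seed, 1),
        )
        if runner.is_cached("simulate", ["projections.tif", "ground_truth_labels.tif",
                                        "ground_truth_islets.csv"]):
            stack = read_projection_stack(stack_path)
            truth = None
        else:
            t0 = time.time()
            sim_dir.mkdir(parents=True, exist_ok=True)
            volume, truth = generate_phantom(phantom_spec)
            stack = forward_project(volume, acq_spec)
            write_projection_stack(stack, stack_path, dtype="float32")
            tifffile.imwrite(sim_dir / "ground_truth_labels.tif",
                             truth.label_volume.astype(np.uint16),
                             photometric="minisblack")
            truth.islet_table.to_csv(sim_dir / "ground_truth_islets.csv", index=False)
            runner.upstream_dirty = True
            runner.record("simulate",
                          _hash_bytes(_params_hash(phantom_spec).encode(),
                                      _params_hash(acq_spec).encode()),
                          {}, ["projections.tif", "ground_truth_labels.tif",
                               "ground_truth_islets.csv"], time.time() - t0)

    # --- preprocess
    pre_dir = runner.stage_dir("preprocess")
    pre_path = pre_dir / "projections.tif"
    if runner.is_cached("preprocess", ["projections.tif"]):
        pre_stack = read_projection_stack(pre_path)
    else:
        t0 = time.time()
        pre_stack = cut_range(stack, config.preprocess)
        if config.preprocess.clahe_enabled:
            pre_stack = clahe(pre_stack, config.preprocess)
        write_projection_stack(pre_stack, pre_path, dtype="float32")
        runner.upstream_dirty = True
        runner.record("preprocess", _params_hash(config.preprocess),
                      {"projections.tif": _hash_file(stack_path)}
                      if stack_path.exists() else {},
                      ["projections.tif"], time.time() - t0)

    # --- align
    ali_dir = runner.stage_dir("align")
    ali_path = ali_dir / "projections.tif"
    if runner.is_cached("align", ["projections.tif", "align.json"]):
        ali_stack = read_projection_stack(ali_path)
    else:
        t0 = time.time()
        result = estimate_cor(pre_stack, max_pairs=64)
        ali_stack = apply_correction(pre_stack, result)
        ali_dir.mkdir(parents=True, exist_ok=True)
        with open(ali_dir / "align.json", "w") as fh:
            json.dump({"cor_offset_px": result.cor_offset_px,
                       "method": result.method,
                       "per_pair_estimates": result.per_pair_estimates}, fh, indent=2)
        write_projection_stack(ali_stack, ali_path, dtype="float32")
        runner.upstream_dirty = True
        runner.record("align", _params_hash({"method": "phase_correlation"}),
                      {"projections.tif": _hash_file(pre_path)},
                      ["projections.tif", "align.json"], time.time() - t0)

    # --- reconstruct
    rec_dir = runner.stage_dir("reconstruct")
    rec_path = rec_dir / "volume.tif"
    if runner.is_cached("reconstruct", ["volume.tif"]):
        volume_rec = read_volume(rec_path)
    else:
        t0 = time.time()
        volume_rec = reconstruct_volume(ali_stack, config.reconstruct)
        write_volume(volume_rec, rec_path)
        runner.upstream_dirty = True
        runner.record("reconstruct", _params_hash(config.reconstruct),
                      {"projections.tif": _hash_file(ali_path)},
                      ["volume.tif"], time.time() - t0)

    # --- segment
    seg_dir = runner.stage_dir("segment")
    seg_outputs = ["tissue_mask.tif", "islet_labels.tif"]
    if config.quantify.tumor:
        seg_outputs.append("low_af_mask.tif")
    if runner.is_cached("segment", seg_outputs):
        labels = read_labels(seg_dir / "islet_labels.tif")
    else:
        t0 = time.time()
        mask = tissue_mask(volume_rec)
        sub = subtract_baseline(volume_rec, config.segment, mask)
        labels = label_islets(sub, config.segment, mask)
        labels = remove_artifacts(labels, config.segment)
        write_mask(mask, volume_rec.voxel_size_scalar_um, seg_dir / "tissue_mask.tif")
        write_labels(labels, seg_dir / "islet_labels.tif")
        if config.quantify.tumor:
            low = delineate_low_af_region(volume_rec, config.segment, mask)
            write_mask(low, volume_rec.voxel_size_scalar_um, seg_dir / "low_af_mask.tif")
        runner.upstream_dirty = True
        runner.record("segment", _params_hash(config.segment),
                      {"volume.tif": _hash_file(rec_path)},
                      seg_outputs, time.time() - t0)

    # --- quantify
    qua_dir = runner.stage_dir("quantify")
    if not runner.is_cached("quantify", ["islets.csv", "distribution.csv"]):
        t0 = time.time()
        records = measure_islets(labels, volume_rec)
        edges = default_category_edges(config.quantify.edges_max_um,
                                       config.quantify.edges_width_um)
        if records:
            # extend the grid in whole bin widths when an unusually large
            # islet exceeds the configured maximum, rather than failing the run
            d_max = max(r.mean_diameter_um for r in records)
            while d_max >= edges[-1]:
                edges = np.append(edges, edges[-1] + config.quantify.edges_width_um)
        dist = size_distribution(records, edges) if records else None
        report = None
        if dist is not None and config.quantify.reference_csv:
            ref = read_reference_distribution(config.quantify.reference_csv)
            report = compare_to_reference(dist, ref)
        export_statistics(records, dist, report, qua_dir)
        outs = ["islets.csv"] + (["distribution.csv"] if dist is not None else [])
        runner.record("quantify", _params_hash(config.quantify),
                      {"islet_labels.tif": _hash_file(seg_dir / "islet_labels.tif")},
                      outs, time.time() - t0)

    return run_dir
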