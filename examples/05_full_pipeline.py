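"""Run the whole chain as one cached, provenance-tracked pipeline.

simulate -> preprocess -> align -> reconstruct -> segment -> quantify,
driven by a single config with one global seed. Re-running with the same
config reuses cached stage outputs; every stage directory carries a
provenance.json with parameter and input hashes.
"""

import json

import numpy as np
import pandas as pd

from aftomo import (AcquisitionSpec, PhantomSpec, PipelineConfig, PreprocessParams,
                    run_pipeline)

config = PipelineConfig(
    seed=5,
    out_dir="example_run",
    phantom=PhantomSpec(shape_vox=(64, 64, 64), n_islets=20, n_vessels=2,
                        islet_diameter_log_mu=np.log(60.0),
                        islet_diameter_log_sigma=0.3, seed=11),
    acquisition=AcquisitionSpec(n_angles=120, cor_offset_px=2.0,
                                noise_model="gaussian", noise_scale=0.02, seed=12),
    preprocess=PreprocessParams(clahe_enabled=False),  # quantitative path
)
run_dir = run_pipeline(config)

align_report = json.load(open(run_dir / "align" / "align.json"))
islets = pd.read_csv(run_dir / "quantify" / "islets.csv")
print(f"run directory: {run_dir}")
print(f"COR offset estimated: {align_report['cor_offset_px']:+.2f} px (true +2.00)")
print(f"islets recovered: {len(islets)} of {config.phantom.n_islets}")
print(f"median mean-diameter: {islets.mean_diameter_um.median():.1f} um")
print("outputs: islets.csv, distribution.csv, islet_labels.tif, volume.tif")
# A second run_pipeline(config) call returns immediately from the cache.
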