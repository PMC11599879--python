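"""Run the whole pipeline from one config and inspect the manifest.

Stages: simulate (multi-epoch scenes + storm tracks) -> sample (transect
records) -> index (A, B, MCPI) -> trend (width OLS per region) -> cena
(clusters + exchange matrix) -> validate (storm NDVI responses). Outputs
land under out_dir with a content-hashed manifest; the same config and
seed always reproduce identical hashes.
"""

import json
from pathlib import Path

from mcpi import RunConfig, run_pipeline

cfg = RunConfig(out_dir=Path("scratch/pipeline_demo"), seed=42)
cfg.epochs = [
    {"year": 2007},
    {"year": 2013, "width_factor": 0.97, "height_factor": 0.90},
    {"year": 2019, "width_factor": 0.95, "height_factor": 0.80, "ndvi_factor": 1.02},
]
cfg.cena.update({"k": 3, "bootstrap": 25})

manifest = run_pipeline(cfg)
print(f"{len(manifest)} artifacts under {cfg.out_dir}")
for entry in manifest:
    if not entry["path"].startswith("scenes/"):
        print(f"  {entry['path']:<28} {entry['sha256'][:12]}…")

summary = json.loads((cfg.out_dir / "validation_summary.json").read_text())
print(f"\nvalidation: rho = {summary['rho']:.3f}, p = {summary['p_value']:.3g}, "
      f"n = {summary['n']}")
# trend.csv holds per-region width slopes across the three epochs;
# cena_exchange.csv the cluster flows between 2007 and 2019. With only a
# handful of storm-region events the correlation here is underpowered —
# example 05 runs the validation at a meaningful sample size (n = 53).
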