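"""Run the whole pipeline into one directory through the file interfaces.

Equivalent to ``pettex run-all``: simulate paired NIfTI volumes, segment
with both threshold rules, extract features, write the agreement reports
and the survival tables, and record a reproducibility manifest.
"""

import json

import pandas as pd

from pettex import RunConfig, run_pipeline

cfg = RunConfig(workdir="scratch/example_run", n_lesions=24, seed=2)
rundir = run_pipeline(cfg)

print(f"run directory: {rundir}")
rep = pd.read_csv(rundir / "agreement_adaptive.csv").set_index("metric")
print(rep[["icc", "precision_pct", "ba_mean_pct", "variation_pct"]].round(3))

with open(rundir / "manifest.json") as fh:
    manifest = json.load(fh)
print(f"\nconfig hash {manifest['config_hash']}  "
      f"(rerunning with this config reproduces every CSV byte-for-byte)")
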