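"""Run the full pipeline from the bundled demo config and show the
manifest proves reproducibility."""

import json
import os
import tempfile

from ecodemarc.pipeline import RunConfig, run_pipeline

config_path = os.path.join(os.path.dirname(__file__), "demo_config.yaml")

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig.from_yaml(config_path)
    cfg.outdir = os.path.join(tmp, "run1")
    m1 = run_pipeline(cfg)
    for stage in m1.stages:
        print(f"{stage['stage']:<11} {json.dumps(stage['params'])[:70]}")

    cfg2 = RunConfig.from_yaml(config_path)
    cfg2.outdir = os.path.join(tmp, "run2")
    m2 = run_pipeline(cfg2)
    same = all(a["outputs"] == b["outputs"]
               for a, b in zip(m1.stages, m2.stages))
    print(f"\nre-run with the same master seed reproduces identical "
          f"checksums: {same}")
    print("Every stage's parameters, seeds and output hashes live in")
    print("manifest.json, so a published run can be re-verified bit for")
    print("bit from its config alone.")
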