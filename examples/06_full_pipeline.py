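"""One-command pipeline run: simulate -> ascertain -> score -> skew ->
segregate -> express, with a deterministic human-readable report.

Equivalent CLI: hbm run --config examples/paper_like.yaml --out-dir hbm_run
"""

from pathlib import Path

from hbmkit import RunConfig, run_pipeline

config = RunConfig.from_yaml(Path(__file__).with_name("paper_like.yaml"))
report = run_pipeline(config)
print(report.text)
print(f"stage outputs written to {report.out_dir}/")
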