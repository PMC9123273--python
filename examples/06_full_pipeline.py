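"""End-to-end pipeline: simulate, split, train both stages, map, report.

Runs the complete two-stage workflow on a small cohort and prints the
headline numbers from the combined report. Equivalent CLI:

    strokekit run-all --out pipeline_demo --seed 7 --n-patients 24

Runtime: a few minutes on one CPU core.
"""

import json

from strokekit import S1Config, S2Config
from strokekit.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    output_dir="pipeline_demo",
    n_patients=24,
    global_seed=7,
    s1=S1Config(epochs=4, seed=0),
    s2=S2Config(seed=0),
    tasks=("size",),
)
report = run_pipeline(config)
print(json.dumps(report["summary"], indent=2))
print("\nartifacts in pipeline_demo/: manifest.tsv, s1_model.npz, segmaps/, "
      "segmentation_metrics.tsv, classification_size.tsv, "
      "lesion_mapping.json, report.json")
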