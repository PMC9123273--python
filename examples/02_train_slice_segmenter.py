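"""Train the Stage One slice segmenter and build per-patient SegMaps.

The 2D U-shaped network segments each axial slice; the per-slice masks
are stacked into a 3D SegMap per patient. Compares the learned
segmentation against the plain intensity-threshold baseline.

Runtime: about two minutes on one CPU core.
"""

import dataclasses

import numpy as np

from strokekit import (PhantomConfig, S1Config, build_s1,
                       generate_atlas_phantom, predict_segmap,
                       simulate_cohort, threshold_segmap, train_s1,
                       zscore_normalize)
from strokekit.metrics import dice

config = PhantomConfig(seed=0)
atlas = generate_atlas_phantom(config, n_regions=6)
cases = simulate_cohort(32, config, atlas, seed=7)
cases = [dataclasses.replace(c, volume=zscore_normalize(c.volume))
         for c in cases]

s1_config = S1Config(epochs=6, seed=0)
model = train_s1(build_s1(s1_config), cases, s1_config, val_fraction=0.25)
print(f"best validation Dice during training: {model.best_val_dice:.3f}")

val_cases = [c for c in cases if c.patient_id in model.val_patient_ids]
for case in val_cases[:4]:
    seg = predict_segmap(model, case.volume)
    baseline = threshold_segmap(case.volume)
    print(f"{case.patient_id}: learned Dice {dice(seg, case.truth_mask):.3f}"
          f"  threshold-baseline Dice "
          f"{dice(baseline, case.truth_mask):.3f}")
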