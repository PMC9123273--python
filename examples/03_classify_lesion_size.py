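"""Train the Stage Two lesion-size classifier from SegMap-guided inputs.

The two-stage classifier sees volume*mask ("extracted stroke area") and
predicts lacune (single lesion, max diameter <= 20 mm) vs non-lacune.
Its decision threshold is set by Youden's index on the internal
validation predictions. A one-stage baseline trained on the full volume
is shown for comparison.

Runtime: about one minute on one CPU core.
"""

import dataclasses

import numpy as np

from strokekit import (PhantomConfig, S2Config, generate_atlas_phantom,
                       predict_class, simulate_cohort, train_one_stage,
                       train_s2, zscore_normalize)
from strokekit.metrics import RankedPredictions, auroc

config = PhantomConfig(seed=0)
atlas = generate_atlas_phantom(config, n_regions=6)
cases = simulate_cohort(64, config, atlas, seed=11)
cases = [dataclasses.replace(c, volume=zscore_normalize(c.volume))
         for c in cases]

s2_config = S2Config(task="size", seed=3)
two_stage = train_s2(cases, [c.truth_mask for c in cases], "size", s2_config)
one_stage = train_one_stage(cases, "size", s2_config)

acc = float(np.mean((two_stage.val_probs >= two_stage.threshold).astype(int)
                    == two_stage.val_labels))
print(f"two-stage validation accuracy: {acc:.3f} "
      f"(threshold {two_stage.threshold:.3f})")
print(f"two-stage validation AUROC: "
      f"{auroc(RankedPredictions(two_stage.val_probs, two_stage.val_labels)):.3f}")
print(f"one-stage validation AUROC: "
      f"{auroc(RankedPredictions(one_stage.val_probs, one_stage.val_labels)):.3f}")

case = cases[0]
pred = predict_class(two_stage, case.volume, case.truth_mask)
print(f"\n{case.patient_id}: predicted {pred.predicted_class} "
      f"(p={pred.probability:.3f}), truth {case.size_label}")
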