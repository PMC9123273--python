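"""Cohort bookkeeping: exclusions, half-up percentages, chronological split.

Builds a screening manifest with exclusion reasons, summarizes it with
the same rounding conventions used in clinical tables (half-up to one
decimal), and splits the analyzed patients 80/20 by acquisition date.
"""

import json
from datetime import date, timedelta

from strokekit import (CohortManifest, ManifestRow, chronological_split,
                       summarize)

day0 = date(2023, 3, 1)
rows = [ManifestRow(f"p{i:03d}", day0 + timedelta(days=i),
                    size_label="lacune" if i % 3 == 0 else "non_lacune",
                    territory_label="anterior" if i % 5 else "posterior")
        for i in range(40)]
rows += [ManifestRow("p900", day0, excluded=True,
                     exclusion_reason="DWI-negative"),
         ManifestRow("p901", day0, excluded=True,
                     exclusion_reason="motion artifact")]

manifest = CohortManifest(rows)
split = chronological_split(manifest, dev_fraction=0.8)
summary = summarize(manifest, split)
print(json.dumps(summary, indent=2))
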