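"""Two-rater, three-replicate ROI measurements and their reliability.

Emulates the manual measurement protocol: each rater places every ROI
three times with small placement noise; replicates are averaged within
rater, then across raters, and the two-rater intraclass correlation
(two-way mixed, single measure, consistency) gates reliability at 0.75.
"""

import numpy as np
import pandas as pd

from dkiasl import average_replicates, icc_two_rater

rng = np.random.default_rng(7)
regions = [f"region-{i:02d}" for i in range(24)]
true_mk = rng.uniform(0.7, 1.1, size=24)  # between-region spread

rows = []
for region, truth in zip(regions, true_mk):
    for rater, bias in ((1, 0.0), (2, 0.02)):  # rater 2 reads slightly high
        for rep in (1, 2, 3):
            rows.append({"subject_id": "subj-01", "region": region,
                         "hemisphere": "left", "metric": "MK",
                         "rater": rater, "replicate": rep,
                         "value": truth + bias + rng.normal(0, 0.01)})
table = pd.DataFrame(rows)

combined, per_rater = average_replicates(table)
wide = per_rater.pivot_table(index="region", columns="rater", values="value")
icc, good = icc_two_rater(wide[1].to_numpy(), wide[2].to_numpy())
print(f"ICC(3,1) over {len(regions)} regions: {icc:.3f} "
      f"({'good' if good else 'below the 0.75 gate'})")
print("The consistency form ignores rater 2's fixed +0.02 offset; only the "
      "replicate placement noise (SD 0.01 against a between-region spread "
      "of ~0.12) lowers it below 1.")
print(combined.head(3).to_string(index=False))
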