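"""Three-group cohort inference on a simulated study.

Generates the default cohort (EC n=33, SCD plus n=27, aMCI n=31) with the
shipped regional effect pattern, then runs the inference stage: per-region
ANOVA (with a normality gate) and Benjamini-Hochberg FDR over the left-
hemisphere MK family, a covariate-adjusted correlation, and a combined
multi-region ROC.
"""

import numpy as np

from dkiasl import (combined_auc, make_cohort, partial_pearson,
                    regionwise_group_analysis)
from dkiasl.stats import metric_column
from dkiasl.synth import CohortConfig

cohort, truth = make_cohort(CohortConfig(seed=42))
print(f"cohort: {len(cohort)} subjects, groups "
      f"{cohort.group.value_counts().to_dict()}")

res = regionwise_group_analysis(cohort, metric="MK", hemisphere="left")
flagged = res[res.reject_fdr]
print("\nleft-hemisphere MK regions surviving BH-FDR (q = 0.05):")
print(flagged[["region", "test_used", "p_raw", "p_fdr"]].to_string(index=False))

sub = cohort[cohort.group == "SCDplus"]
covs = np.column_stack([sub.age, (sub.sex == "F").astype(float), sub.education])
col = metric_column("MK", "left", "Hip (h)")
r, p = partial_pearson(sub[col], sub["AVLT-DR"], covs)
print(f"\nAVLT-DR ~ left Hip (h) MK within SCD plus, adjusted for age/sex/"
      f"education: r = {r:.3f}, p = {p:.4f}")

pair = cohort[cohort.group.isin(["SCDplus", "EC"])]
features = [metric_column("MK", h, rgn) for h, rgn in
            [("left", "Hip (h)"), ("right", "Hip (h)"), ("left", "PCC"),
             ("left", "Pr"), ("left", "DT (a)"), ("left", "OLWM")]]
roc = combined_auc(pair[features], pair.group.to_numpy(), "SCDplus")
print(f"\ncombined MK ROC (SCD plus vs EC over {len(features)} regions): "
      f"AUC = {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")
print("The hippocampal-head deficit drives both the FDR detection and the "
      "positive memory-score correlation; pooling regions through logistic "
      "regression lifts discrimination above any single region.")
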