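"""Paired agreement between the two attenuation-correction variants.

Simulates 20 lesions, applies the HCT -> ACT perturbation (smooth
multiplicative bias, stronger inferiorly, plus reconstruction noise), and
quantifies per-metric agreement: Wilcoxon signed-rank p, ICC(2,1) with
precision (half the 95% CI width, in %), and Bland-Altman percentage
limits with variation = URL - LRL.
"""

import pandas as pd

from pettex import agreement_report, paired_feature_tables

hct, act = paired_feature_tables(n_lesions=20, seed=1)
report = agreement_report(hct, act).set_index("metric")

cols = ["wilcoxon_p", "icc", "precision_pct", "ba_mean_pct", "variation_pct"]
with pd.option_context("display.float_format", "{:8.3f}".format):
    print(report[cols])

stable = report["variation_pct"][["suv_entropy", "glcm_entropy"]].max()
fragile = report["variation_pct"][["contrast", "hglze"]].min()
print(f"\nentropy variation <= {stable:.1f}%  vs  contrast/HGLZE >= {fragile:.1f}%")
# The entropies barely move when the attenuation map changes, while NGTDM
# contrast and HGLZE swing by tens of percent - the robustness ordering
# that makes entropy the safer prognostic candidate.
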