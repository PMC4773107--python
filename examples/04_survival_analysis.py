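"""Dichotomize a texture feature and fit Cox models against survival.

Generates a cohort whose hazard truly depends on SUV entropy (HR 2.69 for
the high stratum), then runs the two-stage workflow: ROC against 3-year
disease-specific survival with a Youden-index cutoff, followed by
univariate and covariate-adjusted Cox models at the Bonferroni threshold
p < 0.017.
"""

import numpy as np
import pandas as pd

from pettex import CohortConfig, generate_survival_cohort, survival_report

rng = np.random.default_rng(7)
n = 56
features = pd.DataFrame(
    {"suv_entropy": rng.normal(3.7, 0.26, n)},
    index=[f"P{i:03d}" for i in range(n)],
)
# a slightly perturbed second variant of the same measurements
features_act = features + rng.normal(0.0, 0.02, (n, 1))

cohort = generate_survival_cohort(
    features["suv_entropy"].to_numpy(),
    CohortConfig(n_patients=n, log_hr=np.log(2.69), seed=2),
).set_index("patient_id")

report = survival_report(cohort, features, features_act, ["suv_entropy"])
print("ROC screening:")
print(report["roc"][["variant", "auc", "cutoff", "sensitivity", "specificity"]])
print("\nUnivariate Cox:")
print(report["cox_univariate"])
print("\nAdjusted Cox (age, cell type, stage, surgery):")
print(report["cox_adjusted"][["variant", "hr", "ci_low", "ci_high", "p", "significant"]])
print("\nCross-variant stratification concordance:")
print(report["concordance"])
# The recovered hazard ratio should sit near the generating value 2.69,
# and both variants should assign almost every patient to the same
# risk stratum.
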