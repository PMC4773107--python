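# pettex

Robustness of PET tumor texture features to the attenuation-correction
map, as a tested, reproducible pipeline.

In PET/CT, the emission data are attenuation-corrected with a CT-derived
map. A helical CT (HCT) is a respiratory snapshot, while a
respiration-averaged CT (ACT, from cine-CT phases) matches the breathing
state of the PET acquisition; the choice changes the reconstructed SUVs,
most strongly near the diaphragm. For radiomics this raises a practical
question: **which texture features survive a change of attenuation map,
and does the choice change survival stratification?** `pettex` provides
everything needed to study that question end-to-end on synthetic paired
data with a known ground truth:

- **Phantoms** — paired pseudo-PET volumes of one lesion under two
  attenuation corrections (a smooth multiplicative bias field, larger in
  inferior slices, plus independent noise), and a survival cohort whose
  hazard truly depends on a chosen feature.
- **Segmentation** — adaptive threshold `0.15 · I_mean70 + background`
  and fixed `T45 = 0.45 · SUVmax`; SUVmax, SUVmean, MTV, TLG.
- **Texture** — 12 features from one 64-bin quantization: SUV entropy
  (histogram); entropy, uniformity, dissimilarity, homogeneity (GLCM);
  coarseness, busyness, contrast, complexity (NGTDM); GLNU, ZSNU, HGLZE
  (GLSZM).
- **Agreement** — Wilcoxon signed-rank, ICC(2,1) with precision (half
  the 95 % CI width), Bland–Altman percentage limits with
  variation = URL − LRL, Spearman |ρ|.
- **Survival** — ROC against 3-year disease-specific survival with
  Youden-index cutoffs, cross-variant stratification concordance, and
  univariate / covariate-adjusted Cox models at the Bonferroni threshold
  p < 0.017.

Volumes and masks travel as NIfTI, tables as CSV, and one master seed
makes every run bit-reproducible.

## Worked example

`examples/04_survival_analysis.py` generates a 56-patient cohort whose
hazard depends on SUV entropy with a true hazard ratio of 2.69, then runs
the two-stage workflow on both correction variants:

```
Univariate Cox:
  variant              term        hr  ...   ci_high         p  significant
0     hct  suv_entropy_high  2.984703  ...  5.489104  0.000435         True
1     act  suv_entropy_high  3.033916  ...  5.633202  0.000439         True

Adjusted Cox (age, cell type, stage, surgery):
  variant        hr    ci_low   ci_high         p  significant
0     hct  2.730838  1.427217  5.225184  0.002410         True
1     act  2.738573  1.436464  5.221002  0.002213         True

Cross-variant stratification concordance:
        metric  concordance
0  suv_entropy     0.982143
```

The recovered hazard ratios bracket the generating value 2.69, both
variants flag the feature significant at α = 0.017, and 55 of the 56
patients land in the same risk stratum under either attenuation map.

`examples/03_paired_agreement.py` shows the other half of the story: on a
20-lesion paired cohort, Bland–Altman variation is ~2–4 % for the two
entropies but tens of percent for NGTDM contrast and HGLZE — entropy is
robust to the attenuation map, the zone/contrast family is not.

The remaining examples cover phantom generation + segmentation, feature
extraction, and the file-based pipeline (also available as a CLI:
`pettex run-all --config demo.yaml`, with `simulate / segment / extract /
agree / survive` subcommands for the individual stages).

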