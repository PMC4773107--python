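# Methods

`pettex` studies how the choice of CT attenuation map — a helical snapshot
(HCT) versus a respiration-averaged map (ACT) — propagates through a PET
radiomics workflow: tumor delineation, texture quantification, paired
agreement statistics, and survival dichotomization. Because the two
corrections are applied to the *same* emission data, every lesion yields a
matched pair of volumes, and the analysis is a paired-agreement problem,
not a group comparison.

## Synthetic data model

### Lesion phantom

A lesion is an ellipsoid of elevated uptake on a low lung background:

- grid 64 × 64 × 48 voxels at 4.46 × 5.46 × 3.27 mm (a typical whole-body
  PET reconstruction geometry); the third axis is craniocaudal with larger
  index = more inferior;
- tumor SUV = base (default 9) + a heterogeneity field: Gaussian white
  noise smoothed with a kernel of σ = 12 mm, centered and scaled to zero
  mean / chosen SD (default 2 SUV) *within the tumor*. Centering matters:
  without it, a lesion sitting in a low swing of the smooth field is
  shifted bodily away from its base value instead of being textured
  around it;
- lung background SUV 0.4, point-spread blur FWHM 6 mm, additive Gaussian
  noise SD 0.15 SUV, values clipped at 0;
- a ~1 cm³ cube of elevated uptake (mean 1.6, SD 0.3 SUV) emulating the
  aortic-arch region used clinically for background measurement. It is
  painted after blur and noise so its first two moments are exactly the
  configured ones;
- the tumor "seed" mask handed to segmentation is the true ellipsoid
  dilated by 2 voxels, emulating a generous manual seed rather than a
  perfect contour.

When a cohort of lesions is sampled (`simulate_paired_cohort`), base SUV
is log-normal around 8 (clipped to 4.5–30 so post-blur SUVmax spans the
clinical range ~3–36 and every lesion clears the adaptive threshold),
semi-axes are uniform 12–24 mm, and centers are uniform over the grid
interior so the inferior bias gradient is exercised.

### Attenuation-map perturbation

The ACT member is `volume × (1 + bias) + noise` with

```
bias = amplitude · G + gradient · z_norm
```

where `G` is a smooth (σ = 40 mm) zero-mean unit-SD random field,
`z_norm` runs 0 (superior) → 1 (inferior), and the noise term (SD 0.1
SUV) is independent reconstruction noise. This emulates the *downstream
effect* of diaphragm misregistration — a smooth multiplicative
rescaling, larger inferiorly and positive on average — and makes no claim
to attenuation physics. Two fidelity properties are targeted: the
direction (expected SUV higher in the ACT member, most so in inferior
slices), and the magnitude, calibrated so that the Bland–Altman variation
of SUVmax over a 40-lesion cohort falls in the 15–35 % range
(amplitude 0.14, gradient 0.03). The per-lesion bias is *not* forced
nonnegative: clinically, individual lesions do come out lower under ACT,
and only the mean shift is positive.

Because the bias is smooth (hence locally nearly affine over a tumor) and
the texture features are invariant to affine intensity rescaling by
construction of the min–max quantization, most of the *texture* variation
between variants is driven by the noise term and by the threshold-induced
change of the delineated VOI — which is exactly the mechanism that makes
histogram/co-occurrence entropy robust and NGTDM contrast or HGLZE
fragile in this model.

### Survival cohort

Event times are exponential with hazard
`h = h0 · exp(β · 1[feature > cutoff] + covariate terms)`, default
`h0 = 0.02 /month` and `β = log 2.69`. Covariates (age, adenocarcinoma,
stage III, radical surgery) are drawn to match a locally advanced NSCLC
cohort (median age ≈ 68, 55 % adeno, 64 % stage III, 52 % surgery) and
carry zero log-hazard by default — they exist so the adjusted Cox model
is exercised, and effects can be switched on per study. Administrative
censoring is uniform on (40.4, 74.8) months; the generator validates that
the window's lower bound is at least the minimum survivor follow-up
(36 months) so every censored record is classifiable at the 3-year
horizon. Non-disease deaths are not simulated; downstream they would be
treated as censoring under the disease-specific endpoint.

All generators draw from numbered substreams of a single integer seed
(`default_rng([seed, k])`), so identical configurations are bit-identical
and components can be regenerated in isolation.

## Segmentation

- **adaptive**: SUVmax is taken within the seed region; `I_mean70` is the
  mean SUV of *all* seed voxels ≥ 0.7 × SUVmax (the simplest reading — a
  connected 70 % isocontour is the plausible alternative);
  `threshold = 0.15 · I_mean70 + background`. If the threshold reaches
  SUVmax the lesion is not delineable and an error is raised.
- **t45**: `threshold = 0.45 × SUVmax`.
- In both cases the VOI is the 26-connected component of voxels
  `≥ threshold` containing the hottest seed voxel. Connectivity is a
  design choice (the convention is rarely stated in clinical toolchains);
  restricting to one component prevents a low adaptive threshold from
  bleeding into other high-uptake structures. Threshold membership is
  inclusive (`≥`), giving deterministic tie behavior.
- MTV is voxel count × voxel volume (cm³); TLG = SUVmean × MTV. Both
  thresholds scale linearly under a positive rescaling of the volume, so
  SUV metrics are scale-covariant and MTV scale-invariant.

## Texture features

One min–max quantization into `n_bins = 64` grey levels feeds all four
representations: `level(v) = floor((v − min)/(max − min) · 64) + 1`,
clamped to 64. Consequences: all 12 features are invariant under
`v → a·v + b, a > 0`, and a constant VOI maps to level 1 everywhere
(handled as a warned degenerate case returning the closed-form constant
vector — entropies 0, uniformity/homogeneity 1, coarseness at its cap,
GLNU = ZSNU = 1, HGLZE = N²).

- **GLCM**: the 13 unique distance-1 3D offsets, both orientations,
  accumulated into a single symmetric matrix normalized to total mass 1
  (merged, not per-direction averaged). Offsets are voxel steps, not mm —
  anisotropy is deliberately ignored, matching common toolbox behavior.
  Features: entropy −ΣP log₂P, uniformity ΣP², dissimilarity Σ|i−j|P,
  homogeneity ΣP/(1+|i−j|).
- **NGTDM**: every VOI voxel with ≥ 1 in-VOI 26-neighbor contributes
  |level − mean neighbor level| to its level's total s(i); p is over
  contributing voxels. Coarseness = 1/(ε + Σpᵢsᵢ) with ε = 10⁻⁶ and a cap
  of 10⁶ for the homogeneous case; contrast, busyness and complexity
  follow the classical visual-texture definitions, with contrast defined
  0 when only one grey level is occupied and busyness 0 when its
  denominator vanishes.
- **GLSZM**: zones are maximal 26-connected equal-level sets;
  GLNU = Σᵢ(row sums)²/N_z, ZSNU = Σⱼ(column sums)²/N_z. HGLZE defaults
  to the jointly emphasized reading Σ i²j²Z(i,j)/N_z; the grey-level-only
  reading Σ i²Z/N_z is available as `hglze_mode="i2"` since published
  formulations differ.

Every matrix builder and feature is tested against independent
brute-force enumerations (per-voxel loops, flood fills) on random masked
grids to 10⁻¹⁰ relative agreement.

## Agreement statistics

Per metric over paired lesions (A = HCT, B = ACT):

- **Wilcoxon signed-rank**, two-sided; zero differences dropped; exact
  null distribution for effective n ≤ 25 with untied |differences|,
  otherwise the tie- and continuity-corrected normal approximation. A
  fully degenerate comparison (all differences zero) reports p = 1 with a
  flag rather than failing.
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures — from the two-way ANOVA mean squares, with the McGraw–Wong
  F-distribution 95 % CI. This flavor is chosen because the scientific
  question is interchangeability of two correction methods (systematic
  shifts must count against agreement); consistency or average-measures
  flavors would answer a different question. *Precision* = half the CI
  width × 100. Degenerate cases: zero between-subject variance → ICC
  undefined (flagged); numerically perfect agreement → ICC 1 with
  zero-width CI.
- **Bland–Altman** on percentage differences `100(B − A)/((A+B)/2)` (the
  pairwise mean as denominator — the standard relative form); limits
  mean ∓/± 1.96 SD; *variation* = URL − LRL = 3.92 SD exactly.
- **Spearman** |ρ| between features, average ranks for ties; constant
  columns yield NaN.

The agreement report has one row per metric: SUVmax, SUVmean, TLG, then
the 12 texture features (15 rows).

## Survival workflow

1. **3-year labels**: death from disease at ≤ 36 months → 1; follow-up
   reaching 36 months (alive, censored later, or death after 36 months)
   → 0; censored before 36 months → excluded with a logged count. The
   synthetic censoring window makes exclusions impossible by design; the
   rule exists for external cohorts.
2. **ROC/Youden**: AUC is the rank statistic; the AUC ≠ 0.5 screen uses
   the DeLong paired-rank variance with a two-sided normal test at
   α = 0.05. Cutoff candidates are midpoints between adjacent sorted
   unique values; orientation is auto-detected (so protective features
   like coarseness, where *low* values are high-risk, are handled), and
   Youden ties break toward higher specificity — the conservative,
   smaller high-risk group.
3. **Cox PH** via lifelines with Efron tie handling (Newton settings
   tightened to precision 10⁻¹⁴ so estimates match a direct
   partial-likelihood maximization to ~10⁻⁶; Breslow is not offered —
   lifelines implements Efron only). Wald CIs on the log scale,
   exponentiated. Each multivariable model contains exactly one
   dichotomized texture term plus the four clinical covariates — never
   two texture terms, which are strongly collinear.
4. **Significance** at the Bonferroni-corrected α = 0.05/3 = 0.017
   (three texture terms tested per variant).
5. **Stratification concordance**: fraction of lesions assigned the same
   risk stratum by the two variants under their own cutoffs.

## Problem sizes and what the tests show

The Monte-Carlo suites run at desk scale chosen by the package: the
robustness-ordering experiment uses 40 lesions × 20 seeds, agreement
type-I error 2000 null replicates at n = 56, survival recovery 100 seeds
at n = 500 (the acceptance script uses 10 and 40 seeds for the same
experiments). These sizes give stable pass/fail behavior for the stated
bands; they are not estimates of clinical effect sizes.

Passing tests demonstrate internal correctness (matrices equal brute
force, statistics equal their definitions, the generator's parameters are
recovered) and the *qualitative* robustness structure — entropies moving
far less than NGTDM contrast or HGLZE under a smooth attenuation bias.
They do not validate the perturbation model against real cine-CT
attenuation maps: real misregistration artifacts are not smooth
multiplicative fields, tumors are not ellipsoids with Gaussian texture,
and scanner PSF is spatially varying. Quantitative agreement values from
the simulation (ICCs, variations) therefore characterize the model, not
any scanner.

## Known limitations

- No attenuation/scatter physics, no respiratory-gated (4D) acquisition,
  no DICOM I/O, no nodal lesions, no multi-lesion splitting.
- Quantization is fixed-bin-number min–max; fixed-bin-width strategies
  (which break affine invariance) are not implemented.
- The NGTDM/GLSZM definitions follow one classical formulation each;
  harmonized-standard variants differ in normalization details.
- `wilcoxon_signed_rank` delegates to scipy and inherits its exact-method
  tie policy; `spearman_matrix` reports NaN rather than estimating under
  degeneracy.
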