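"""Synthetic paired PET data and linked survival cohorts.

This module fabricates the three ingredients the downstream analysis
needs, with the statistical structure the analysis assumes:

1. A lung-like PET phantom: an ellipsoidal tumor of elevated SUV with a
   spatially correlated heterogeneity field, a low-uptake lung background,
   a high-uptake reference structure (emulating the aortic arch used for
   background measurement), point-spread blurring and additive noise.
2. An attenuation-correction perturbation that maps the "helical CT"
   (HCT) variant of a lesion onto a "respiration-averaged CT" (ACT)
   variant: a smooth multiplicative bias field whose expected magnitude
   grows toward inferior slices, mimicking diaphragm-misregistration
   artifacts, plus independent reconstruction noise. Both variants come
   from the same emission data, so the perturbation is the *only* source
   of disagreement.
3. A survival cohort whose hazard depends on a chosen texture feature
   through a step function at a true cutoff — an exponential proportional
   hazards model that the survival module should be able to invert.

All randomness flows from one integer seed per operation; internally each
independent draw uses a numbered substream (``default_rng([seed, k])``) so
components can be regenerated in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import PetVolume

__all__ = [
    "PhantomConfig",
    "PerturbationConfig",
    "CohortConfig",
    "generate_phantom",
    "apply_attenuation_perturbation",
    "generate_survival_cohort",
    "simulate_paired_cohort",
    "COHORT_COLUMNS",
]

_AXES = "xyz"

COHORT_COLUMNS = ["patient_id", "time_months", "event", "age", "adeno", "stage3", "surgery"]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Substream `stream` of the generator family rooted at `seed`."""
    return np.random.default_rng([int(seed), int(stream)])


def _smooth_unit_field(shape, spacing, corr_mm, rng, normalize_over=None) -> np.ndarray:
    """White noise smoothed by a Gaussian kernel of sigma `corr_mm`, centered
    and rescaled to zero mean / unit sample SD over `normalize_over` voxels
    (or the whole grid)."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sel = smooth[normalize_over] if normalize_over is not None else smooth
    sd = sel.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - sel.mean()) / sd


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity model of one synthetic lesion.

    Defaults mirror a clinical whole-body PET reconstruction: a
    64 x 64 x 48 grid at 4.46 x 5.46 x 3.27 mm voxels, a ~1.8 cm-radius
    tumor of base SUV 9 with SD-2 heterogeneity, lung background around
    SUV 0.4 and a mediastinal reference structure of SUV 1.6 +/- 0.3.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (4.46, 5.46, 3.27)
    tumor_center_mm: tuple[float, float, float] | None = None  # None -> grid center
    tumor_semiaxes_mm: tuple[float, float, float] = (18.0, 18.0, 18.0)
    tumor_suv: float = 9.0
    heterogeneity_amplitude: float = 2.0
    heterogeneity_corr_mm: float = 12.0
    lung_suv: float = 0.4
    background_ref_suv: float = 1.6
    background_ref_sd: float = 0.3
    psf_fwhm_mm: float = 6.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError("tumor semi-axes must be > 0")
        if self.heterogeneity_amplitude < 0:
            raise ValueError("heterogeneity amplitude must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.background_ref_suv <= self.lung_suv:
            raise ValueError("background-reference mean must exceed lung mean")
        if any(n < 8 for n in self.shape):
            raise ValueError("grid must be >= 8 voxels per axis")


@dataclass(frozen=True)
class PerturbationConfig:
    """Attenuation-map perturbation HCT -> ACT.

    ``bias_amplitude`` is the SD of the smooth zero-mean multiplicative
    bias (fraction of SUV); ``inferior_gradient`` adds
    ``gradient * z/(nz-1)`` so inferior slices are biased upward, which is
    where misregistration artifacts concentrate. ``noise_sd`` is additive
    SUV noise independent between the two reconstructions.
    """

    bias_amplitude: float = 0.14
    bias_corr_mm: float = 40.0
    inferior_gradient: float = 0.03
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_amplitude < 0:
            raise ValueError("bias amplitude must be >= 0")
        if self.inferior_gradient < 0:
            raise ValueError("inferior gradient weight must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Exponential proportional-hazards cohort linked to one feature.

    Hazard per patient: ``baseline_hazard * exp(beta * [feature > cutoff]
    + covariate terms)`` with uniform administrative censoring on
    ``censoring_window`` months. Covariate distributions default to the
    clinical mix of a locally advanced NSCLC cohort (median age 68,
    55% adenocarcinoma, 64% stage III, 52% radical surgery); covariate
    log-hazard effects default to zero.
    """

    n_patients: int = 56
    feature_name: str = "suv_entropy"
    cutoff: float | None = None  # None -> median of supplied features
    log_hr: float = float(np.log(2.69))
    baseline_hazard: float = 0.02  # events / month in the low-risk stratum
    age_mean: float = 66.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (34.0, 84.0)
    p_adeno: float = 0.554
    p_stage3: float = 0.643
    p_surgery: float = 0.518
    covariate_log_hrs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    # (per-year age effect about age_mean, adeno, stage3, surgery)
    censoring_window: tuple[float, float] = (40.4, 74.8)
    min_followup: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        lo, hi = self.censoring_window
        if hi <= self.min_followup:
            raise ValueError("censoring window upper bound must exceed minimum follow-up")
        if lo < self.min_followup:
            raise ValueError(
                "censoring window lower bound must be >= minimum survivor follow-up "
                "so censored records satisfy the follow-up guarantee"
            )
        if lo >= hi:
            raise ValueError("censoring window must be a nonempty interval")


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


def generate_phantom(config: PhantomConfig) -> tuple[PetVolume, np.ndarray, np.ndarray]:
    """Build one lesion and return ``(volume, tumor_seed_mask, background_ref_mask)``.

    The tumor interior is ``tumor_suv`` plus a smoothed random field scaled
    to the requested SD; the whole scene is blurred by the PSF FWHM, noise
    is added and values clipped at zero. The reference structure (a ~1 cm^3
    cube of elevated uptake) is painted last so its mean/SD match the
    configured aortic-arch statistics exactly rather than post-blur. The
    seed mask is the true ellipsoid dilated by 2 voxels, emulating a
    generous manual seed region.
    """
    shape, spacing = config.shape, config.spacing
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    center = (
        tuple(e / 2 for e in extent)
        if config.tumor_center_mm is None
        else tuple(config.tumor_center_mm)
    )
    for ax in range(3):
        if center[ax] - config.tumor_semiaxes_mm[ax] < 0 or (
            center[ax] + config.tumor_semiaxes_mm[ax] > extent[ax]
        ):
            raise ValueError(
                f"tumor ellipsoid clipped by grid boundary along axis '{_AXES[ax]}'"
            )

    r2 = sum(
        ((c - cc) / a) ** 2
        for c, cc, a in zip(coords, center, config.tumor_semiaxes_mm)
    )
    tumor = r2 <= 1.0

    vol = np.full(shape, config.lung_suv, dtype=np.float64)
    vol[tumor] = config.tumor_suv
    if config.heterogeneity_amplitude > 0:
        het = _smooth_unit_field(
            shape, spacing, config.heterogeneity_corr_mm, _rng(config.seed, 0),
            normalize_over=tumor,
        )
        vol[tumor] += config.heterogeneity_amplitude * het[tumor]

    if config.psf_fwhm_mm > 0:
        sigma = [config.psf_fwhm_mm / 2.3548200450309493 / s for s in spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma, mode="nearest")
    if config.noise_sd > 0:
        vol += config.noise_sd * _rng(config.seed, 2).standard_normal(shape)

    # reference cube ~1 cm^3, fixed near the corner opposite nothing in
    # particular: far from the (central) tumor for default geometries
    n_ref = [max(1, int(round(10.0 / s))) for s in spacing]
    origin = [4, 4, shape[2] // 2]
    ref = np.zeros(shape, dtype=bool)
    ref[
        origin[0] : origin[0] + n_ref[0],
        origin[1] : origin[1] + n_ref[1],
        origin[2] : origin[2] + n_ref[2],
    ] = True
    if (ref & tumor).any():
        raise ValueError("tumor overlaps the background-reference region; move the center")
    vol[ref] = config.background_ref_suv + config.background_ref_sd * _rng(
        config.seed, 1
    ).standard_normal(int(ref.sum()))

    vol = np.clip(vol, 0.0, None)
    seed_mask = ndimage.binary_dilation(tumor, iterations=2)
    return PetVolume(values=vol, spacing=spacing), seed_mask, ref


def apply_attenuation_perturbation(
    volume: PetVolume, config: PerturbationConfig
) -> PetVolume:
    """Map an HCT-corrected volume onto its ACT-corrected counterpart.

    ``out = volume * (1 + bias) + noise`` with
    ``bias = amplitude * G + gradient * z_norm`` where ``G`` is a smooth
    zero-mean unit-SD field and ``z_norm`` runs 0 (superior) to 1
    (inferior). The gradient term makes the *expected* bias positive and
    largest in the lower lung; individual lesions may still come out lower
    in the ACT member, as seen clinically. Amplitude 0 with noise 0 is an
    exact identity.
    """
    if config.bias_amplitude == 0 and config.inferior_gradient == 0 and config.noise_sd == 0:
        return volume
    shape, spacing = volume.shape, volume.spacing
    bias = np.zeros(shape)
    if config.bias_amplitude > 0:
        bias += config.bias_amplitude * _smooth_unit_field(
            shape, spacing, config.bias_corr_mm, _rng(config.seed, 0)
        )
    if config.inferior_gradient > 0:
        z_norm = np.arange(shape[2]) / max(shape[2] - 1, 1)
        bias += config.inferior_gradient * z_norm[None, None, :]
    out = volume.values * (1.0 + bias)
    if config.noise_sd > 0:
        out = out + config.noise_sd * _rng(config.seed, 1).standard_normal(shape)
    return volume.with_values(np.clip(out, 0.0, None))


# ---------------------------------------------------------------------------
# paired lesion cohort
# ---------------------------------------------------------------------------


def simulate_paired_cohort(
    n_lesions: int,
    seed: int = 0,
    phantom_template: PhantomConfig | None = None,
    perturbation_template: PerturbationConfig | None = None,
):
    """Sample `n_lesions` lesions with per-lesion geometry/intensity variation
    and return a list of dicts ``{lesion_id, hct, act, seed_mask, bg_mask}``.

    Per-lesion draws: base SUV log-normal spanning roughly SUVmax 3-36,
    semi-axes 12-24 mm, tumor center jittered in-plane and uniform over the
    central craniocaudal range (so the inferior bias gradient is exercised).
    """
    pt = phantom_template or PhantomConfig()
    qt = perturbation_template or PerturbationConfig()
    master = _rng(seed, 1000)
    lesions = []
    extent = [(n - 1) * s for n, s in zip(pt.shape, pt.spacing)]
    for i in range(n_lesions):
        # bounded so post-blur SUVmax spans roughly the clinical 3-36 range
        # and every lesion clears the adaptive threshold
        base = float(np.clip(np.exp(master.normal(np.log(8.0), 0.45)), 4.5, 30.0))
        semis = tuple(float(master.uniform(12.0, 24.0)) for _ in range(3))
        margin = [a + 3 * s for a, s in zip(semis, pt.spacing)]
        center = tuple(
            float(master.uniform(margin[ax], extent[ax] - margin[ax])) for ax in range(3)
        )
        pcfg = PhantomConfig(
            **{
                **asdict(pt),
                "tumor_center_mm": center,
                "tumor_semiaxes_mm": semis,
                "tumor_suv": base,
                "heterogeneity_amplitude": pt.heterogeneity_amplitude * base / 8.0,
                "seed": int(master.integers(0, 2**31 - 1)),
            }
        )
        qcfg = PerturbationConfig(
            **{**asdict(qt), "seed": int(master.integers(0, 2**31 - 1))}
        )
        hct, seed_mask, bg_mask = generate_phantom(pcfg)
        act = apply_attenuation_perturbation(hct, qcfg)
        lesions.append(
            {
                "lesion_id": f"L{i:03d}",
                "hct": hct,
                "act": act,
                "seed_mask": seed_mask,
                "bg_mask": bg_mask,
                "phantom_config": pcfg,
                "perturbation_config": qcfg,
            }
        )
    return lesions


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------


def generate_survival_cohort(features, config: CohortConfig) -> pd.DataFrame:
    """Draw one survival record per feature value.

    Returns a DataFrame with columns ``patient_id, time_months, event, age,
    adeno, stage3, surgery`` (events are disease-specific deaths; censored
    records all have time >= the minimum survivor follow-up).
    """
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim != 1 or len(feats) != config.n_patients:
        raise ValueError(
            f"need exactly one feature value per patient "
            f"({config.n_patients}), got {feats.shape}"
        )
    cutoff = float(np.median(feats)) if config.cutoff is None else float(config.cutoff)
    high = feats > cutoff
    if high.all() or (~high).all():
        warnings.warn(
            "all patients fall on one side of the cutoff; the feature hazard "
            "ratio is not recoverable from this cohort",
            stacklevel=2,
        )

    rng = _rng(config.seed, 0)
    n = config.n_patients
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    )
    adeno = rng.random(n) < config.p_adeno
    stage3 = rng.random(n) < config.p_stage3
    surgery = rng.random(n) < config.p_surgery

    b_age, b_adeno, b_stage3, b_surgery = config.covariate_log_hrs
    lp = (
        config.log_hr * high
        + b_age * (age - config.age_mean)
        + b_adeno * adeno
        + b_stage3 * stage3
        + b_surgery * surgery
    )
    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(*config.censoring_window, n)
    event = (t_event <= t_cens).astype(int)
    time = np.where(event == 1, t_event, t_cens)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "age": age,
            "adeno": adeno.astype(int),
            "stage3": stage3.astype(int),
            "surgery": surgery.astype(int),
        }
    )
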