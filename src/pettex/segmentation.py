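"""Tumor delineation and SUV metrics.

Two threshold rules are supported:

* **adaptive** — ``threshold = 0.15 * I_mean70 + background``, where
  ``I_mean70`` is the mean SUV over seed-region voxels at or above 70% of
  the lesion SUVmax and ``background`` is the mean SUV of a reference
  region (the aortic arch clinically).
* **t45** — a fixed threshold at 45% of SUVmax.

In both cases the volume of interest (VOI) is the 26-connected component
of above-threshold voxels that contains the hottest seed voxel; threshold
membership is inclusive (>=). Restricting to one component keeps a low
adaptive threshold from bleeding into unrelated high-uptake structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import PetVolume

__all__ = [
    "SegmentationResult",
    "measure_background",
    "adaptive_threshold_segment",
    "t45_segment",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationResult:
    """A delineated VOI and its SUV metrics.

    MTV is the VOI volume in cm^3 (voxel count x voxel volume); TLG is
    SUVmean x MTV. ``background_mean`` and ``i_mean70`` are filled only by
    the adaptive method.
    """

    method: str
    threshold: float
    mask: np.ndarray
    suvmax: float
    suvmean: float
    mtv_cm3: float
    tlg: float
    background_mean: float | None = None
    i_mean70: float | None = None


def measure_background(volume: PetVolume, reference_mask: np.ndarray) -> float:
    """Arithmetic mean SUV over the reference region."""
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("reference mask shape does not match the volume")
    if not mask.any():
        raise ValueError("reference mask is empty")
    return float(volume.values[mask].mean())


def _component_of(above: np.ndarray, index: tuple[int, int, int]) -> np.ndarray:
    labels, _ = ndimage.label(above, structure=_CONN26)
    return labels == labels[index]


def _finish(volume: PetVolume, voi: np.ndarray, method: str, threshold: float,
            suvmax: float, **extra) -> SegmentationResult:
    if not voi.any():
        raise ValueError(f"{method} segmentation produced an empty VOI")
    vals = volume.values[voi]
    mtv = int(voi.sum()) * volume.voxel_volume_cm3
    suvmean = float(vals.mean())
    return SegmentationResult(
        method=method,
        threshold=float(threshold),
        mask=voi,
        suvmax=float(suvmax),
        suvmean=suvmean,
        mtv_cm3=mtv,
        tlg=suvmean * mtv,
        **extra,
    )


def adaptive_threshold_segment(
    volume: PetVolume, seed_mask: np.ndarray, background_mean: float
) -> SegmentationResult:
    """Delineate with the background-adapted threshold.

    SUVmax and ``I_mean70`` are evaluated within the seed region; the
    70%-of-max region is every seed voxel >= 0.7 * SUVmax (not only a
    connected isocontour).
    """
    seed = np.asarray(seed_mask, dtype=bool)
    if not seed.any():
        raise ValueError("seed mask is empty")
    if background_mean < 0:
        raise ValueError("background mean must be >= 0")
    vals = volume.values
    seed_vals = vals[seed]
    suvmax = float(seed_vals.max())
    i70 = float(seed_vals[seed_vals >= 0.7 * suvmax].mean())
    threshold = 0.15 * i70 + background_mean
    if threshold >= suvmax:
        raise ValueError("threshold exceeds lesion maximum")
    # hottest voxel within the seed region anchors the component
    masked = np.where(seed, vals, -np.inf)
    hottest = np.unravel_index(int(np.argmax(masked)), vals.shape)
    voi = _component_of(vals >= threshold, hottest)
    return _finish(
        volume, voi, "adaptive", threshold, suvmax,
        background_mean=float(background_mean), i_mean70=i70,
    )


def t45_segment(volume: PetVolume, seed_mask: np.ndarray) -> SegmentationResult:
    """Delineate at the fixed 45%-of-SUVmax threshold."""
    seed = np.asarray(seed_mask, dtype=bool)
    if not seed.any():
        raise ValueError("seed mask is empty")
    vals = volume.values
    suvmax = float(vals[seed].max())
    threshold = 0.45 * suvmax
    masked = np.where(seed, vals, -np.inf)
    hottest = np.unravel_index(int(np.argmax(masked)), vals.shape)
    voi = _component_of(vals >= threshold, hottest)
    return _finish(volume, voi, "t45", threshold, suvmax)
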