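"""Texture features of a quantized tumor VOI.

The VOI is min-max resampled once into ``n_bins`` grey levels (default 64)
and four representations are built from that single quantization:

* the grey-level **histogram** (SUV entropy);
* the normalized **grey-level co-occurrence matrix** (GLCM) over the 13
  unique 3D voxel offsets at Chebyshev distance 1, accumulated into one
  symmetric matrix (entropy, uniformity, dissimilarity, homogeneity);
* the **neighborhood grey-tone difference matrix** (NGTDM): for every VOI
  voxel with at least one in-VOI 26-neighbor, the absolute difference
  between its level and the mean level of those neighbors, summed per
  level (coarseness, busyness, contrast, complexity);
* the **grey-level size-zone matrix** (GLSZM): counts of maximal
  26-connected equal-level zones by level and size (grey-level
  nonuniformity, zone-size nonuniformity, high grey-level large zone
  emphasis).

Offsets and neighborhoods are measured in voxel steps, not millimetres;
anisotropic spacing is deliberately ignored at this stage, matching common
toolbox practice.

Because quantization is min-max based, every feature is invariant under a
positive affine rescaling of the SUVs — the representations depend only on
grey levels, never on the underlying intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .segmentation import SegmentationResult
from .volume import PetVolume

__all__ = [
    "QuantizedVoi",
    "GlcmMatrix",
    "NgtdmTable",
    "GlszmMatrix",
    "TextureFeatureSet",
    "FEATURE_NAMES",
    "quantize",
    "quantize_voi",
    "suv_entropy",
    "build_glcm",
    "glcm_features",
    "build_ngtdm",
    "ngtdm_features",
    "build_glszm",
    "glszm_features",
    "extract_all",
]

#: small constant guarding the coarseness reciprocal; cap for the
#: perfectly homogeneous case
NGTDM_EPS = 1e-6
COARSENESS_CAP = 1e6

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: the 13 unique distance-1 offsets (half of the 26-neighborhood)
OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantizedVoi:
    """VOI grey levels on the grid plus the level histogram.

    ``levels`` holds integers in ``{1..n_bins}`` inside ``mask`` and 0
    outside. ``p`` is the length-``n_bins`` probability vector
    ``n_i / N`` indexed so that ``p[i-1]`` belongs to level ``i``.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    counts: np.ndarray
    p: np.ndarray
    n_voxels: int


def quantize(values, n_bins: int = 64) -> np.ndarray:
    """Map SUVs to grey levels 1..n_bins by min-max resampling.

    ``level(v) = floor((v - min) / (max - min) * n_bins) + 1`` clamped to
    ``n_bins`` (so the maximum lands in the top bin); a constant input maps
    everything to level 1.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot quantize an empty value set")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        return np.ones(v.shape, dtype=np.int64)
    lev = np.floor((v - vmin) / (vmax - vmin) * n_bins).astype(np.int64) + 1
    return np.minimum(lev, n_bins)


def quantize_voi(volume: PetVolume | np.ndarray, mask: np.ndarray,
                 n_bins: int = 64) -> QuantizedVoi:
    """Quantize the masked voxels of a volume, keeping the grid layout."""
    vals = volume.values if isinstance(volume, PetVolume) else np.asarray(volume, float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("VOI mask is empty")
    voi_vals = vals[mask]
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[mask] = quantize(voi_vals, n_bins)
    counts = np.bincount(levels[mask], minlength=n_bins + 1)[1:]
    n = int(mask.sum())
    vmin, vmax = voi_vals.min(), voi_vals.max()
    edges = np.linspace(vmin, vmax, n_bins + 1) if vmin < vmax else np.array([vmin, vmax])
    return QuantizedVoi(
        levels=levels, mask=mask, n_bins=n_bins, bin_edges=edges,
        counts=counts, p=counts / n, n_voxels=n,
    )


def suv_entropy(q: QuantizedVoi) -> float:
    """Shannon entropy (bits) of the grey-level histogram."""
    p = q.p[q.p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlcmMatrix:
    """Symmetric normalized co-occurrence probabilities, indexed 1-based
    via ``P[i-1, j-1]``."""

    P: np.ndarray
    n_bins: int


@dataclass(frozen=True)
class GlcmFeatures:
    entropy: float
    uniformity: float
    dissimilarity: float
    homogeneity: float


def build_glcm(q: QuantizedVoi) -> GlcmMatrix:
    """Accumulate level pairs over all 13 offsets (both orientations) where
    both voxels are inside the VOI, then normalize to total mass 1."""
    counts = np.zeros((q.n_bins, q.n_bins), dtype=np.float64)
    lev, mask = q.levels, q.mask
    for off in OFFSETS_13:
        src = tuple(
            slice(max(-o, 0), lev.shape[ax] - max(o, 0)) for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(o, 0), lev.shape[ax] - max(-o, 0)) for ax, o in enumerate(off)
        )
        both = mask[src] & mask[dst]
        a = lev[src][both] - 1
        b = lev[dst][both] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("VOI too small/disconnected for co-occurrence")
    return GlcmMatrix(P=counts / total, n_bins=q.n_bins)


def glcm_features(m: GlcmMatrix) -> GlcmFeatures:
    P = m.P
    nz = P[P > 0]
    i, j = np.indices(P.shape)
    absdiff = np.abs(i - j)
    return GlcmFeatures(
        entropy=float(-(nz * np.log2(nz)).sum()),
        uniformity=float((P**2).sum()),
        dissimilarity=float((absdiff * P).sum()),
        homogeneity=float((P / (1.0 + absdiff)).sum()),
    )


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NgtdmTable:
    """Per-level difference totals ``s[i-1]`` and probabilities ``p[i-1]``
    over the contributing voxels (those with >= 1 in-VOI neighbor)."""

    s: np.ndarray
    p: np.ndarray
    n_gp: int
    n: int
    n_bins: int


@dataclass(frozen=True)
class NgtdmFeatures:
    coarseness: float
    busyness: float
    contrast: float
    complexity: float


def build_ngtdm(q: QuantizedVoi) -> NgtdmTable:
    lev = q.levels.astype(np.float64)
    mask = q.mask
    kernel = _CONN26.astype(np.float64).copy()
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(lev * mask, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    contrib = mask & (nbr_cnt > 0.5)
    if not contrib.any():
        raise ValueError("no VOI voxel has an in-mask neighbor")
    abar = nbr_sum[contrib] / nbr_cnt[contrib]
    lv = q.levels[contrib]
    diff = np.abs(lv - abar)
    s = np.bincount(lv, weights=diff, minlength=q.n_bins + 1)[1:]
    counts = np.bincount(lv, minlength=q.n_bins + 1)[1:]
    n = int(contrib.sum())
    p = counts / n
    return NgtdmTable(s=s, p=p, n_gp=int((counts > 0).sum()), n=n, n_bins=q.n_bins)


def ngtdm_features(t: NgtdmTable, eps: float = NGTDM_EPS,
                   cap: float = COARSENESS_CAP) -> NgtdmFeatures:
    levels = np.arange(1, t.n_bins + 1, dtype=np.float64)
    occ = t.p > 0
    i = levels[occ]
    pi = t.p[occ]
    si = t.s[occ]
    psum = float((pi * si).sum())

    coarseness = min(1.0 / (eps + psum), cap)

    if t.n_gp <= 1:
        contrast = 0.0
    else:
        pij = pi[:, None] * pi[None, :]
        contrast = float(
            (pij * (i[:, None] - i[None, :]) ** 2).sum()
            / (t.n_gp * (t.n_gp - 1))
            * (t.s.sum() / t.n)
        )

    ipi = i * pi
    denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = 0.0 if denom == 0 else psum / denom

    pis = pi * si
    complexity = float(
        (
            np.abs(i[:, None] - i[None, :])
            * (pis[:, None] + pis[None, :])
            / (t.n * (pi[:, None] + pi[None, :]))
        ).sum()
    )
    return NgtdmFeatures(
        coarseness=float(coarseness), busyness=float(busyness),
        contrast=contrast, complexity=complexity,
    )


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlszmMatrix:
    """Zone counts ``Z[i-1, j-1]`` = number of 26-connected zones of level
    ``i`` and size ``j``; column index runs 1..max zone size."""

    Z: np.ndarray
    n_bins: int
    n_z: int
    n: int


@dataclass(frozen=True)
class GlszmFeatures:
    glnu: float
    zsnu: float
    hglze: float


def build_glszm(q: QuantizedVoi) -> GlszmMatrix:
    zones: list[tuple[int, int]] = []
    for level in np.flatnonzero(q.counts) + 1:
        labels, n_lab = ndimage.label(q.levels == level, structure=_CONN26)
        if n_lab:
            sizes = np.bincount(labels.ravel())[1:]
            zones.extend((int(level), int(sz)) for sz in sizes)
    max_size = max(sz for _, sz in zones)
    Z = np.zeros((q.n_bins, max_size), dtype=np.int64)
    for level, sz in zones:
        Z[level - 1, sz - 1] += 1
    return GlszmMatrix(Z=Z, n_bins=q.n_bins, n_z=len(zones), n=q.n_voxels)


def glszm_features(z: GlszmMatrix, hglze_mode: str = "i2j2") -> GlszmFeatures:
    """Summaries of the zone matrix.

    ``hglze_mode='i2j2'`` (default) jointly emphasizes high grey level and
    large zone size, ``sum(i^2 j^2 Z)/N_z``; ``'i2'`` is the grey-level-only
    reading ``sum(i^2 Z)/N_z``.
    """
    if z.n_z < 1:
        raise ValueError("zone matrix has no zones")
    row = z.Z.sum(axis=1).astype(np.float64)
    col = z.Z.sum(axis=0).astype(np.float64)
    i2 = np.arange(1, z.n_bins + 1, dtype=np.float64) ** 2
    j2 = np.arange(1, z.Z.shape[1] + 1, dtype=np.float64) ** 2
    if hglze_mode == "i2j2":
        hglze = float((i2[:, None] * j2[None, :] * z.Z).sum() / z.n_z)
    elif hglze_mode == "i2":
        hglze = float((i2 * row).sum() / z.n_z)
    else:
        raise ValueError(f"unknown hglze_mode {hglze_mode!r}")
    return GlszmFeatures(
        glnu=float((row**2).sum() / z.n_z),
        zsnu=float((col**2).sum() / z.n_z),
        hglze=hglze,
    )


# ---------------------------------------------------------------------------
# the 12-feature set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextureFeatureSet:
    suv_entropy: float
    glcm_entropy: float
    uniformity: float
    dissimilarity: float
    homogeneity: float
    coarseness: float
    busyness: float
    contrast: float
    complexity: float
    glnu: float
    zsnu: float
    hglze: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = [f.name for f in fields(TextureFeatureSet)]


def _constant_feature_set(n_voxels: int) -> TextureFeatureSet:
    return TextureFeatureSet(
        suv_entropy=0.0, glcm_entropy=0.0, uniformity=1.0, dissimilarity=0.0,
        homogeneity=1.0, coarseness=COARSENESS_CAP, busyness=0.0, contrast=0.0,
        complexity=0.0, glnu=1.0, zsnu=1.0, hglze=float(n_voxels) ** 2,
    )


def extract_all(volume: PetVolume, seg: SegmentationResult, n_bins: int = 64,
                hglze_mode: str = "i2j2") -> TextureFeatureSet:
    """Quantize the VOI once and compute all 12 features.

    A degenerate VOI (a single voxel, or constant SUV) returns the
    closed-form constant-lesion feature vector with a warning instead of
    erroring, so batch runs survive flat lesions.
    """
    mask = seg.mask
    vals = volume.values
    # crop to the bounding box: the representations only see in-mask voxels
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_mask = mask[box]
    sub_vals = vals[box]

    voi_vals = sub_vals[sub_mask]
    if sub_mask.sum() == 1 or voi_vals.min() == voi_vals.max():
        warnings.warn("degenerate VOI (constant or single-voxel); returning "
                      "the constant-lesion feature vector", stacklevel=2)
        return _constant_feature_set(int(sub_mask.sum()))

    q = quantize_voi(sub_vals, sub_mask, n_bins)
    g = glcm_features(build_glcm(q))
    ng = ngtdm_features(build_ngtdm(q))
    gz = glszm_features(build_glszm(q), hglze_mode=hglze_mode)
    return TextureFeatureSet(
        suv_entropy=suv_entropy(q),
        glcm_entropy=g.entropy, uniformity=g.uniformity,
        dissimilarity=g.dissimilarity, homogeneity=g.homogeneity,
        coarseness=ng.coarseness, busyness=ng.busyness,
        contrast=ng.contrast, complexity=ng.complexity,
        glnu=gz.glnu, zsnu=gz.zsnu, hglze=gz.hglze,
    )
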