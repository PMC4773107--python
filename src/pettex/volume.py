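"""3D PET volumes in SUV units with anisotropic voxel spacing.

The in-memory container is a thin immutable wrapper around a numpy array,
with NIfTI round-tripping through nibabel. Axis convention: arrays are
indexed ``(x, y, z)`` where the third axis is craniocaudal and a *larger*
index is more *inferior* (toward the diaphragm). The convention tag travels
with the volume so downstream code can assert it instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: default tag; the only convention this package produces
XYZ_Z_INFERIOR = "xyz:z-index-increases-inferior"


@dataclass(frozen=True)
class PetVolume:
    """A 3D grid of standardized uptake values.

    Parameters
    ----------
    values
        SUV per voxel, shape ``(nx, ny, nz)``, all finite and >= 0.
    spacing
        Voxel edge lengths in mm along each axis, all > 0.
    axis_convention
        Tag recording how axes map to patient anatomy.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    axis_convention: str = XYZ_Z_INFERIOR

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={arr.ndim}")
        if any(n < 8 for n in arr.shape):
            raise ValueError(f"each axis must have >= 8 voxels, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite")
        if arr.min() < 0:
            raise ValueError("SUV values must be >= 0")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (product of spacings in mm / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray) -> "PetVolume":
        """Same geometry, new voxel values."""
        return PetVolume(values=values, spacing=self.spacing,
                         axis_convention=self.axis_convention)

    # ---- NIfTI I/O -------------------------------------------------------

    def _affine(self) -> np.ndarray:
        return np.diag([self.spacing[0], self.spacing[1], self.spacing[2], 1.0])

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values, self._affine()), str(path))

    @classmethod
    def load(cls, path) -> "PetVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        # tiny negative excursions can appear through scl_slope round trips
        return cls(values=np.clip(data, 0.0, None), spacing=spacing)


def save_mask(mask: np.ndarray, spacing: tuple[float, float, float], path) -> None:
    """Write a binary mask as a 0/1 uint8 NIfTI volume."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5
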