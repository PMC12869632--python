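"""HU clipping, attenuation-based normalization, slice selection, NIfTI I/O.

CT intensities are clipped to [-1000, 1600] HU (air through dense
contrast-enhanced tissue), converted to linear attenuation via the water
attenuation constant mu_w = 0.192 cm^-1 (mu = mu_w * (1 + HU/1000)), and
affinely rescaled so the clip window maps onto [-1, 1]. Because the
HU-to-attenuation map is itself affine, the composition is an affine map of
clipped HU — the only mapping consistent with both the mu_w parameterisation
and the stated [-1, 1] output range.

Slice selection follows the training-data protocol: keep every ``stride``-th
slice of a volume, then retain slices with at least ``min_liver_pixels``
liver pixels (counting happens after subsampling).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CTSlice2D

__all__ = [
    "NormalizationSpec", "SliceSelectionSpec",
    "clip_hu", "normalize", "denormalize", "select_slices",
    "normalize_slice", "write_subject_volume", "read_subject_volume",
    "read_slice", "read_cohort",
]


@dataclass(frozen=True)
class NormalizationSpec:
    hu_min: float = -1000.0
    hu_max: float = 1600.0
    mu_water: float = 0.192  # cm^-1

    def __post_init__(self):
        if not self.hu_min < self.hu_max:
            raise ValueError("hu_min must be < hu_max")
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")

    def mu(self, hu):
        """Linear attenuation coefficient for a given HU value."""
        return self.mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


@dataclass(frozen=True)
class SliceSelectionSpec:
    stride: int = 3
    min_liver_pixels: int = 100

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.min_liver_pixels < 0:
            raise ValueError("min_liver_pixels must be >= 0")


def clip_hu(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if np.any(np.isnan(image)):
        raise ValueError("image contains NaN pixels")
    return np.clip(image, spec.hu_min, spec.hu_max)


def normalize(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Map clipped HU to [-1, 1] through the attenuation parameterisation."""
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < spec.hu_min - 1e-9) or np.any(image > spec.hu_max + 1e-9):
        raise ValueError("normalize expects an already clipped image")
    mu = spec.mu(image)
    mu_lo, mu_hi = spec.mu(spec.hu_min), spec.mu(spec.hu_max)
    return 2.0 * (mu - mu_lo) / (mu_hi - mu_lo) - 1.0


def denormalize(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Inverse of :func:`normalize`; rejects values outside [-1, 1] beyond 1e-6."""
    image = np.asarray(image, dtype=np.float64)
    if np.any(np.abs(image) > 1.0 + 1e-6):
        raise ValueError("denormalize expects values in [-1, 1]")
    mu_lo, mu_hi = spec.mu(spec.hu_min), spec.mu(spec.hu_max)
    mu = (image + 1.0) / 2.0 * (mu_hi - mu_lo) + mu_lo
    return (mu / spec.mu_water - 1.0) * 1000.0


def normalize_slice(sl: CTSlice2D, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Clip + normalize a slice's HU grid (masks are untouched)."""
    return normalize(clip_hu(sl.image, spec), spec)


def select_slices(volume, spec: SliceSelectionSpec = SliceSelectionSpec()):
    """Subsample every ``stride``-th slice, then apply the liver-pixel retention rule."""
    retained = []
    for idx in range(0, len(volume), spec.stride):
        sl = volume[idx]
        mask = getattr(sl, "liver_mask", None)
        if mask is None:
            raise ValueError(f"slice at position {idx} carries no liver mask")
        if int(np.asarray(mask).sum()) >= spec.min_liver_pixels:
            retained.append(sl)
    return retained


# ---------------------------------------------------------------------------
# NIfTI I/O (slice stacking order: slice_index ascending along axis 2)
# ---------------------------------------------------------------------------

def _subject_paths(directory, subject_id):
    directory = Path(directory)
    return {
        "image": directory / f"{subject_id}_image.nii.gz",
        "liver": directory / f"{subject_id}_liver.nii.gz",
        "tumor": directory / f"{subject_id}_tumor.nii.gz",
    }


def write_subject_volume(directory, subject_id: str, slices: list[CTSlice2D]) -> dict:
    paths = _subject_paths(directory, subject_id)
    affine = np.eye(4)
    img = np.round(np.stack([s.image for s in slices], axis=2)).astype(np.int16)
    liv = np.stack([s.liver_mask for s in slices], axis=2).astype(np.uint8)
    tum = np.stack([s.tumor_mask for s in slices], axis=2).astype(np.uint8)
    nib.save(nib.Nifti1Image(img, affine), paths["image"])
    nib.save(nib.Nifti1Image(liv, affine), paths["liver"])
    nib.save(nib.Nifti1Image(tum, affine), paths["tumor"])
    return paths


def read_subject_volume(directory, subject_id: str) -> list[CTSlice2D]:
    paths = _subject_paths(directory, subject_id)
    try:
        img = np.asarray(nib.load(paths["image"]).dataobj)
        liv = np.asarray(nib.load(paths["liver"]).dataobj)
        tum = np.asarray(nib.load(paths["tumor"]).dataobj) if paths["tumor"].exists() \
            else np.zeros_like(liv)
    except OSError as exc:
        raise OSError(f"failed reading subject {subject_id} under {directory}: {exc}") from exc
    return [CTSlice2D(image=img[:, :, k].astype(np.float64),
                      liver_mask=(liv[:, :, k] > 0).astype(np.uint8),
                      tumor_mask=(tum[:, :, k] > 0).astype(np.uint8),
                      subject_id=subject_id, slice_index=k)
            for k in range(img.shape[2])]


def read_slice(directory, subject_id: str, slice_index: int) -> CTSlice2D:
    vol = read_subject_volume(directory, subject_id)
    if not (0 <= slice_index < len(vol)):
        raise IndexError(f"slice_index {slice_index} out of range for {subject_id}")
    return vol[slice_index]


def read_cohort(directory, manifest_name: str = "manifest.tsv") -> list[CTSlice2D]:
    """Load a cohort written by :func:`hepanomaly.phantom.write_cohort`, in manifest order."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / manifest_name, sep="\t")
    volumes: dict[str, list[CTSlice2D]] = {}
    out = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        if sid not in volumes:
            volumes[sid] = read_subject_volume(directory, sid)
        out.append(volumes[sid][int(row["slice_index"])])
    return out
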