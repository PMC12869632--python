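"""Synthetic abdominal CT phantoms with liver and lesion masks.

The generator emulates the features of an axial portal-venous abdominal CT
slice that the downstream pipeline actually depends on: an air background, a
body-shaped soft-tissue support with a subcutaneous fat rim, a connected
star-convex liver with textured parenchyma in a plausible soft-tissue HU
band, a few extrahepatic structures (spine, aorta, a gastric shadow) so that
inpainting has anatomical context, and optional hypodense lesions of
controllable pixel area placed fully inside the liver. It makes no attempt
at physically realistic CT simulation (no beam hardening, no 3-D anatomy,
no contrast-phase effects).

Lesion areas are exact by construction: the lesion support is the set of the
A smallest values of a smooth radial field, so the tumor mask contains
exactly A pixels while the rendered lesion keeps a soft 1-2 px edge, which
is what makes low lesion-to-liver contrast a nontrivial detection problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import PhantomSlice

__all__ = ["PhantomParams", "PhantomSlice", "generate_phantom", "generate_cohort", "write_cohort"]

HU_MIN, HU_MAX = -1000.0, 1600.0


@dataclass
class PhantomParams:
    """Controls for one phantom slice; defaults give a 64 px desk-scale slice."""

    image_size: int = 64
    body_hu: float = 40.0
    liver_hu: float = 60.0
    texture_sd: float = 10.0
    n_lesions: int = 1
    lesion_area_range: tuple[int, int] = (12, 160)
    lesion_contrast: float = -40.0  # signed HU offset from liver mean; negative = hypodense
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.lesion_area_range
        if not (1 <= lo <= hi):
            raise ValueError("lesion_area_range must satisfy 1 <= min <= max")
        # star-convex liver radius is ~0.23 * image_size; cap lesions at that area
        max_area = math.pi * (0.23 * self.image_size) ** 2
        if hi > max_area:
            raise ValueError(
                f"lesion_area_range max {hi} exceeds liver area achievable "
                f"at image_size {self.image_size} (~{int(max_area)} px)")
        for name in ("body_hu", "liver_hu"):
            v = getattr(self, name)
            if not (HU_MIN <= v <= HU_MAX):
                raise ValueError(f"{name}={v} outside clip window [{HU_MIN}, {HU_MAX}]")
        if not (HU_MIN <= self.liver_hu + self.lesion_contrast <= HU_MAX):
            raise ValueError("lesion mean HU outside clip window")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


@dataclass
class _Anatomy:
    """Per-subject geometry, fixed across that subject's slices."""

    body_axes: tuple[float, float]
    body_center: tuple[float, float]
    liver_center: tuple[float, float]
    liver_r0: float
    liver_harmonics: np.ndarray  # (k_max, 2): amplitude, phase per harmonic
    organ_seeds: np.ndarray


def _sample_anatomy(rng: np.random.Generator, params: PhantomParams) -> _Anatomy:
    s = params.image_size
    return _Anatomy(
        body_axes=(0.42 * s * rng.uniform(0.95, 1.05), 0.46 * s * rng.uniform(0.95, 1.05)),
        body_center=(0.5 * s, 0.5 * s),
        liver_center=(0.42 * s + rng.uniform(-1.5, 1.5), 0.38 * s + rng.uniform(-1.5, 1.5)),
        liver_r0=0.23 * s * rng.uniform(0.92, 1.05),
        liver_harmonics=np.column_stack([
            rng.uniform(0.02, 0.07, size=4), rng.uniform(0, 2 * math.pi, size=4)]),
        organ_seeds=rng.integers(0, 2**31 - 1, size=4),
    )


def _polar(shape, center):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    return np.hypot(dr, dc), np.arctan2(dr, dc)


def _star_blob(shape, center, r0, harmonics) -> np.ndarray:
    """Star-convex blob: ellipse radius modulated by low-order Fourier terms."""
    d, theta = _polar(shape, center)
    radius = np.full(shape, r0)
    for k, (amp, phase) in enumerate(harmonics, start=2):
        radius *= 1.0 + amp * np.cos(k * theta + phase)
    return d <= radius


def _texture(rng, shape, sd, smooth=0.7):
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
    std = noise.std()
    return noise * (sd / std) if std > 0 else noise


def _insert_lesion(rng, image, liver_mask, tumor_mask, area, contrast, edge=1.5):
    """Place one soft-edged radial-falloff lesion of exactly ``area`` pixels.

    Returns True on success; False when no admissible center exists.
    """
    r_est = math.sqrt(area / math.pi)
    # wobble stretches the radius by up to ~13%; the soft edge is clipped to the liver
    margin = 1.13 * r_est + 1.0
    dist_in = ndimage.distance_transform_edt(liver_mask)
    allowed = (dist_in >= margin) & ~ndimage.binary_dilation(tumor_mask, iterations=2)
    centers = np.argwhere(allowed)
    if len(centers) == 0:
        return False
    for _ in range(30):
        cy, cx = centers[rng.integers(len(centers))]
        d, theta = _polar(image.shape, (float(cy), float(cx)))
        # mild shape perturbation so lesions are not perfect disks
        wobble = 1.0 + 0.08 * np.cos(2 * theta + rng.uniform(0, 2 * math.pi)) \
            + 0.05 * np.cos(3 * theta + rng.uniform(0, 2 * math.pi))
        d_eff = d / np.maximum(wobble, 0.5)
        r_star = np.partition(d_eff.ravel(), area - 1)[area - 1]
        mask = d_eff <= r_star
        if mask.sum() != area:  # float ties; extremely unlikely
            continue
        if np.any(mask & ~liver_mask.astype(bool)) or np.any(mask & tumor_mask.astype(bool)):
            continue
        weight = np.clip((r_star + edge - d_eff) / edge, 0.0, 1.0) * liver_mask
        image += contrast * weight
        tumor_mask |= mask
        return True
    return False


def _render_slice(anatomy: _Anatomy, rng: np.random.Generator, params: PhantomParams,
                  lesion_areas: list[int], subject_id: str, slice_index: int) -> PhantomSlice:
    s = params.image_size
    shape = (s, s)
    jitter = rng.uniform(0.97, 1.03)

    d_body, _ = _polar(shape, anatomy.body_center)
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    ay, ax = anatomy.body_axes
    body_field = ((rr - anatomy.body_center[0]) / (ay * jitter)) ** 2 + \
                 ((cc - anatomy.body_center[1]) / (ax * jitter)) ** 2
    body = body_field <= 1.0
    fat_rim = (body_field <= 1.0) & (body_field > 0.78)

    image = np.full(shape, HU_MIN)
    image[body] = params.body_hu + _texture(rng, shape, 5.0)[body]
    image[fat_rim] = -100.0 + _texture(rng, shape, 6.0)[fat_rim]

    liver_mask = _star_blob(shape, anatomy.liver_center, anatomy.liver_r0 * jitter,
                            anatomy.liver_harmonics)
    liver_mask &= body
    image[liver_mask] = params.liver_hu + _texture(rng, shape, params.texture_sd)[liver_mask]

    # extrahepatic context: spine, aorta, gastric shadow (positions per subject)
    org_rng = np.random.default_rng(anatomy.organ_seeds[0])
    spine_c = (0.82 * s + org_rng.uniform(-1, 1), 0.5 * s + org_rng.uniform(-1, 1))
    d_sp, _ = _polar(shape, spine_c)
    spine = (d_sp <= 0.06 * s) & body & ~liver_mask
    image[spine] = 350.0 + _texture(rng, shape, 20.0)[spine]
    aorta_c = (0.68 * s + org_rng.uniform(-1, 1), 0.56 * s + org_rng.uniform(-1, 1))
    d_ao, _ = _polar(shape, aorta_c)
    aorta = (d_ao <= 0.035 * s) & body & ~liver_mask
    image[aorta] = 180.0 + _texture(rng, shape, 8.0)[aorta]
    stom_c = (0.40 * s + org_rng.uniform(-2, 2), 0.68 * s + org_rng.uniform(-2, 2))
    stomach = _star_blob(shape, stom_c, 0.10 * s,
                         np.column_stack([org_rng.uniform(0.02, 0.08, 3),
                                          org_rng.uniform(0, 2 * math.pi, 3)]))
    stomach &= body & ~liver_mask & ~spine & ~aorta
    image[stomach] = -60.0 + _texture(rng, shape, 8.0)[stomach]

    tumor_mask = np.zeros(shape, dtype=bool)
    for area in lesion_areas:
        ok = _insert_lesion(rng, image, liver_mask, tumor_mask, int(area), params.lesion_contrast)
        if not ok:
            raise ValueError(
                f"cannot place lesion of area {area} px inside generated liver "
                f"({int(liver_mask.sum())} px): infeasible configuration")

    image = np.clip(image, HU_MIN, HU_MAX)
    return PhantomSlice(image=image, liver_mask=liver_mask.astype(np.uint8),
                        tumor_mask=tumor_mask.astype(np.uint8),
                        subject_id=subject_id, slice_index=slice_index)


def _lesion_areas_for(rng, params, n):
    lo, hi = params.lesion_area_range
    areas = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    return [int(round(a)) for a in np.clip(areas, lo, hi)]


def generate_phantom(params: PhantomParams) -> PhantomSlice:
    """Generate one phantom slice; bit-deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    anatomy = _sample_anatomy(rng, params)
    areas = _lesion_areas_for(rng, params, params.n_lesions)
    return _render_slice(anatomy, rng, params, areas, subject_id="S000", slice_index=0)


def generate_cohort(n_subjects: int, slices_per_subject: int, lesion_fraction: float,
                    params: PhantomParams) -> list[PhantomSlice]:
    """Generate a multi-subject cohort suitable for grouped cross-validation.

    Exactly ``round(lesion_fraction * n_slices)`` slices carry lesions, spread
    uniformly at random across the cohort. Lesion areas are sampled
    log-uniformly within ``params.lesion_area_range``, cycling through four
    equal log-width sub-bands so that quartile binning of the generated areas
    is populated across the full size range.
    """
    if n_subjects < 1 or slices_per_subject < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 <= lesion_fraction <= 1.0):
        raise ValueError("lesion_fraction must be in [0, 1]")
    master = np.random.SeedSequence(params.seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    n_total = n_subjects * slices_per_subject
    n_lesioned = int(round(lesion_fraction * n_total))
    lesioned = np.zeros(n_total, dtype=bool)
    lesioned[assign_rng.permutation(n_total)[:n_lesioned]] = True

    lo, hi = params.lesion_area_range
    log_edges = np.linspace(math.log(lo), math.log(hi), 5)
    subject_seeds = master.spawn(n_subjects)

    cohort: list[PhantomSlice] = []
    flat = 0
    band = 0
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(subject_seeds[i])
        anatomy = _sample_anatomy(sub_rng, params)
        sid = f"S{i:03d}"
        for j in range(slices_per_subject):
            if lesioned[flat] and params.n_lesions > 0:
                areas = []
                for _ in range(params.n_lesions):
                    a, b = log_edges[band % 4], log_edges[band % 4 + 1]
                    band += 1
                    areas.append(int(round(math.exp(sub_rng.uniform(a, b)))))
            else:
                areas = []
            cohort.append(_render_slice(anatomy, sub_rng, params, areas, sid, j))
            flat += 1
    return cohort


def write_cohort(cohort: list[PhantomSlice], directory) -> pd.DataFrame:
    """Write one NIfTI image+mask volume per subject plus a TSV manifest.

    Images are stored as int16 HU (slice_index ascending along the third
    axis), masks as uint8, so integer-HU phantoms round-trip losslessly
    through :func:`hepanomaly.preprocess.read_slice`. Returns the manifest.
    """
    from . import preprocess  # deferred: avoids an import cycle at module load

    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[PhantomSlice]] = {}
    for sl in cohort:
        by_subject.setdefault(sl.subject_id, []).append(sl)
    rows = []
    for sid, slices in by_subject.items():
        slices = sorted(slices, key=lambda s: s.slice_index)
        try:
            preprocess.write_subject_volume(directory, sid, slices)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing subject {sid} under {directory}: {exc}") from exc
        for sl in slices:
            rows.append({"subject_id": sid, "slice_index": sl.slice_index,
                         "lesion_area_px": sl.tumor_area})
    manifest = pd.DataFrame(rows, columns=["subject_id", "slice_index", "lesion_area_px"])
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest
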