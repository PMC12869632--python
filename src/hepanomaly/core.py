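"""Shared data containers for the liver-CT anomaly-detection pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary {0,1}")
    return mask.astype(np.uint8)


@dataclass
class CTSlice2D:
    """One axial CT slice: HU pixel grid plus aligned organ/tumor masks.

    ``image`` is in Hounsfield units; ``liver_mask`` and ``tumor_mask`` are
    binary grids on the same pixel lattice ((row, col), 0-based). A slice
    without lesion annotation carries an all-zero ``tumor_mask``.
    """

    image: np.ndarray
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    subject_id: str
    slice_index: int

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.liver_mask = _as_binary(self.liver_mask)
        self.tumor_mask = _as_binary(self.tumor_mask)
        if not (self.image.shape == self.liver_mask.shape == self.tumor_mask.shape):
            raise ValueError("image and masks must share dimensions")
        if np.any(self.tumor_mask & ~self.liver_mask.astype(bool)):
            raise ValueError("tumor_mask must lie inside liver_mask")

    @property
    def liver_pixels(self) -> int:
        return int(self.liver_mask.sum())

    @property
    def tumor_area(self) -> int:
        return int(self.tumor_mask.sum())


# Phantom slices are ordinary CT slices; the alias names the provenance.
PhantomSlice = CTSlice2D


@dataclass
class SlicePairRecord:
    """Aligned (original, inpainted, liver-mask) triple in normalized units.

    ``original`` and ``inpainted`` live in the model's [-1, 1] range;
    ``tumor_mask`` (optional, may be all-zero) travels along for evaluation
    and for the training-purity guard of the reconstructor.
    """

    original: np.ndarray
    inpainted: np.ndarray
    liver_mask: np.ndarray
    subject_id: str
    slice_index: int
    tumor_mask: np.ndarray | None = None

    def __post_init__(self):
        self.liver_mask = _as_binary(self.liver_mask)
        if not (self.original.shape == self.inpainted.shape == self.liver_mask.shape):
            raise ValueError("original, inpainted and liver_mask must share dimensions")
        if self.liver_mask.sum() == 0:
            raise ValueError("liver_mask must be nonempty")
        if self.tumor_mask is not None:
            self.tumor_mask = _as_binary(self.tumor_mask)


@dataclass
class AnomalyResult:
    """Liver-scoped anomaly output: continuous score map, binary map, threshold."""

    score_map: np.ndarray
    binary_map: np.ndarray
    threshold: float
    params: object = None

    def __post_init__(self):
        self.binary_map = _as_binary(self.binary_map)
        if np.any(self.score_map < 0):
            raise ValueError("score_map must be nonnegative")


@dataclass
class EvalRecord:
    """Per-slice evaluation metrics, all computed within the liver mask."""

    subject_id: str
    slice_index: int
    dice: float
    iou: float
    hd95: float  # np.nan flags the undefined (empty-mask) case
    auroc: float
    tumor_area: int
    fold_id: int = -1
    extra: dict = field(default_factory=dict)
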