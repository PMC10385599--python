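"""Lung-field masks: repair, quality control, and Dice scoring.

Automatically generated lung masks occasionally contain pinhole artifacts or
miss a lung field entirely.  The repair operator closes pinholes with
morphological closing followed by filling of interior holes below a minimum
area; the QC operator rejects masks that do not show two lung fields.

Connectivity conventions: foreground connected components use 8-connectivity,
interior holes use 4-connectivity (the standard dual pairing, which prevents
diagonal leaks between foreground and background).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .image import require_same_shape

QC_PASS = "pass"
QC_FAIL_CONTOUR_COUNT = "fail_contour_count"
QC_FAIL_VISIBILITY = "fail_visibility"

#: structuring element side for morphological closing (in pixels)
DEFAULT_CLOSING_KERNEL = 8
#: holes smaller than this fraction of the image area are filled
DEFAULT_MIN_AREA_FRACTION = 1.0 / 16.0
#: second-largest/largest component area ratio below which a lung field is
#: considered poorly visible
DEFAULT_MIN_MINOR_RATIO = 0.25


@dataclass
class LungMask:
    """Binary lung-field mask with derived component/hole inventories."""

    pixels: np.ndarray
    qc_status: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniques = np.unique(arr)
            if not np.isin(uniques, (0, 1, 255)).all():
                raise ValueError("mask pixels must be binary (0/1 or 0/255)")
            arr = arr > 0
        self.pixels = arr

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def component_areas(self) -> List[int]:
        """Foreground component areas (8-connectivity), largest first."""
        labels = measure.label(self.pixels, connectivity=2)
        if labels.max() == 0:
            return []
        areas = np.bincount(labels.ravel())[1:]
        return sorted((int(a) for a in areas), reverse=True)

    def hole_areas(self) -> List[int]:
        """Areas of background components not touching the border (4-conn)."""
        return [int(hole.sum()) for hole in _iter_holes(self.pixels)]

    def to_uint8(self) -> np.ndarray:
        """8-bit {0, 255} representation used on disk."""
        return np.where(self.pixels, 255, 0).astype(np.uint8)


def _iter_holes(pixels: np.ndarray):
    """Yield boolean grids, one per interior hole (4-connectivity)."""
    background = ~pixels
    labels = measure.label(background, connectivity=1)
    if labels.max() == 0:
        return
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border_labels = set(int(b) for b in border_labels if b != 0)
    for lab in range(1, labels.max() + 1):
        if lab not in border_labels:
            yield labels == lab


def repair_mask(
    mask: LungMask,
    closing_kernel: int = DEFAULT_CLOSING_KERNEL,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
) -> LungMask:
    """Close pinholes and fill small interior holes.

    Morphological closing with a ``closing_kernel`` x ``closing_kernel``
    square structuring element is applied first, then every interior hole
    whose area is below ``min_area_fraction`` of the total image area is
    filled.  Holes at or above the threshold are preserved.  The output
    foreground is always a superset of the input foreground, and the
    operation is idempotent at fixed parameters.
    """
    if not (0.0 < min_area_fraction <= 1.0):
        raise ValueError(
            f"min_area_fraction must be in (0, 1], got {min_area_fraction}"
        )
    if closing_kernel < 1:
        raise ValueError("closing_kernel must be >= 1")
    pixels = mask.pixels
    # Pad before closing so the structuring element never interacts with the
    # image border: this keeps closing extensive (output superset of input).
    pad = closing_kernel
    padded = np.pad(pixels, pad, mode="constant", constant_values=False)
    structure = np.ones((closing_kernel, closing_kernel), dtype=bool)
    closed = ndi.binary_closing(padded, structure=structure)
    closed = closed[pad:-pad, pad:-pad]
    closed = closed | pixels

    threshold = min_area_fraction * pixels.size
    filled = closed.copy()
    for hole in _iter_holes(closed):
        if hole.sum() < threshold:
            filled |= hole
    return LungMask(filled)


def qc_mask(mask: LungMask, min_minor_ratio: float = DEFAULT_MIN_MINOR_RATIO) -> str:
    """Quality-control a (repaired) lung mask.

    Returns ``"fail_contour_count"`` if fewer than two foreground components
    are present, ``"fail_visibility"`` if the second-largest component is
    smaller than ``min_minor_ratio`` times the largest (one lung field poorly
    visible), else ``"pass"``.  The status is also written to
    ``mask.qc_status``.
    """
    areas = mask.component_areas()
    if len(areas) < 2:
        status = QC_FAIL_CONTOUR_COUNT
    elif areas[1] < min_minor_ratio * areas[0]:
        status = QC_FAIL_VISIBILITY
    else:
        status = QC_PASS
    mask.qc_status = status
    return status


def dice(a: LungMask, b: LungMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Returns 1.0 when both masks are empty (perfect agreement convention).
    """
    require_same_shape(a.pixels, b.pixels, "masks")
    total = a.area + b.area
    if total == 0:
        return 1.0
    intersection = int((a.pixels & b.pixels).sum())
    return 2.0 * intersection / total
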