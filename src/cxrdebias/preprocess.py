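"""Per-image homogenization operators.

The canonical operator order is fixed: histogram equalization, lung-field
mask application, close cropping, rib suppression.  Ablation configurations
toggle operator inclusion but never reorder them.  Equalization is applied
once, before masking, so the black background introduced by segmentation
never dominates the histogram.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import NoContentError
from .image import RadiographImage, require_same_shape
from .segmask import LungMask


def equalize_histogram(image: RadiographImage) -> RadiographImage:
    """Global histogram equalization by empirical-CDF mapping.

    Each value ``v`` maps to ``round((cdf(v) - cdf_min) / (1 - cdf_min) *
    (L - 1))`` over ``L = 2**bit_depth`` bins, where ``cdf_min`` is the CDF
    at the smallest occurring value.  The mapping is monotone non-decreasing,
    so pixel rank order is preserved.  Constant images are returned
    unchanged (the CDF is degenerate and the mapping undefined).
    """
    pixels = image.pixels
    levels = 1 << image.bit_depth
    hist = np.bincount(pixels.ravel(), minlength=levels)
    cdf = np.cumsum(hist) / pixels.size
    cdf_min = cdf[np.flatnonzero(hist)[0]]
    if cdf_min >= 1.0:  # constant image: degenerate CDF, no-op by convention
        return image.with_pixels(pixels.copy())
    lut = np.rint((cdf - cdf_min) / (1.0 - cdf_min) * (levels - 1))
    lut = np.clip(lut, 0, levels - 1).astype(pixels.dtype)
    return image.with_pixels(lut[pixels])


def apply_mask(image: RadiographImage, mask: LungMask) -> RadiographImage:
    """Zero every pixel outside the lung-field mask."""
    require_same_shape(image.pixels, mask.pixels, "image and mask")
    return image.with_pixels(np.where(mask.pixels, image.pixels, 0))


def content_bbox(pixels: np.ndarray) -> Tuple[int, int, int, int]:
    """Inclusive bounding box (r0, r1, c0, c1) of non-zero pixels."""
    nz_rows = np.flatnonzero(pixels.any(axis=1))
    nz_cols = np.flatnonzero(pixels.any(axis=0))
    if len(nz_rows) == 0:
        raise NoContentError("image contains no non-zero pixel")
    return int(nz_rows[0]), int(nz_rows[-1]), int(nz_cols[0]), int(nz_cols[-1])


def crop_to_content(image: RadiographImage) -> RadiographImage:
    """Crop to the minimal bounding box of non-zero pixels.

    After cropping, every border row/column contains at least one non-zero
    pixel; the operation is idempotent.
    """
    r0, r1, c0, c1 = content_bbox(image.pixels)
    return image.with_pixels(image.pixels[r0 : r1 + 1, c0 : c1 + 1].copy())


@dataclass(frozen=True)
class PipelineFlags:
    """Operator toggles for the canonical pipeline (equalization always on)."""

    segmentation: bool = False
    cropping: bool = False
    rib_suppression: bool = False


def run_image_pipeline(
    image: RadiographImage,
    flags: PipelineFlags,
    mask: Optional[LungMask] = None,
    suppressor=None,
) -> RadiographImage:
    """Apply the canonical operator sequence with the given toggles.

    Order is always equalize -> mask -> crop -> suppress regardless of how
    the flags were assembled.
    """
    from .suppress import suppress_ribs  # local import to avoid a cycle

    out = equalize_histogram(image)
    if flags.segmentation:
        if mask is None:
            raise ValueError("segmentation requested but no mask supplied")
        out = apply_mask(out, mask)
    if flags.cropping:
        out = crop_to_content(out)
    if flags.rib_suppression:
        if suppressor is None:
            raise ValueError("rib suppression requested but no suppressor supplied")
        out = suppress_ribs(out, suppressor)
    return out
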