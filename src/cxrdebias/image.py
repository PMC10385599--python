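"""Radiograph image container.

Pixels are stored as non-negative integers at a declared bit depth (8, 12 or
16), matching how chest radiographs are stored on disk; numerical operators
work on a normalized float copy in [0, 1] obtained via :meth:`to_float`.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ShapeMismatchError

VALID_BIT_DEPTHS = (8, 12, 16)


@dataclass
class RadiographImage:
    """A 2-D grayscale radiograph.

    Parameters
    ----------
    pixels:
        2-D integer array; values must lie in ``[0, 2**bit_depth - 1]``.
    bit_depth:
        One of 8, 12 or 16.
    source_id:
        Free-text identifier of the acquisition site / repository.
    label:
        Optional class label (``"nodule"`` or ``"non-nodule"``).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("pixels must be non-empty")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {VALID_BIT_DEPTHS}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("pixels must have an integer dtype; use from_float()")
        if arr.min() < 0 or arr.max() > self.max_value:
            raise ValueError(
                f"pixel values outside [0, {self.max_value}] for bit depth "
                f"{self.bit_depth}"
            )
        self.pixels = arr

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def to_float(self) -> np.ndarray:
        """Normalized float copy in [0, 1]."""
        return self.pixels.astype(np.float64) / self.max_value

    @classmethod
    def from_float(
        cls,
        pixels: np.ndarray,
        bit_depth: int = 8,
        source_id: str = "",
        label: Optional[str] = None,
    ) -> "RadiographImage":
        """Quantize a float array in [0, 1] to the requested bit depth."""
        arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
        max_value = (1 << bit_depth) - 1
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        quantized = np.rint(arr * max_value).astype(dtype)
        return cls(quantized, bit_depth=bit_depth, source_id=source_id, label=label)

    def with_pixels(self, pixels: np.ndarray) -> "RadiographImage":
        """Copy of this image with new pixel data but unchanged metadata."""
        return replace(self, pixels=pixels)


def require_same_shape(a: np.ndarray, b: np.ndarray, what: str = "grids") -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"{what} have different shapes: {a.shape} vs {b.shape}")
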