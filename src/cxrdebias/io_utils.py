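"""Grayscale PNG and DICOM readers/writers."""
from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .errors import UnsupportedFormatError
from .image import RadiographImage
from .segmask import LungMask


def write_png(image: RadiographImage, path) -> Path:
    """Write a radiograph as an 8- or 16-bit grayscale PNG.

    12-bit data is stored in a 16-bit container (values unscaled).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if image.bit_depth == 8:
        pil = PILImage.fromarray(image.pixels.astype(np.uint8), mode="L")
    else:
        pil = PILImage.fromarray(image.pixels.astype(np.uint16))
    pil.save(path)
    return path


def read_png(path, bit_depth: int | None = None, source_id: str = "") -> RadiographImage:
    """Read an 8- or 16-bit grayscale PNG as a RadiographImage."""
    path = Path(path)
    pil = PILImage.open(path)
    if pil.mode in ("L",):
        arr = np.asarray(pil, dtype=np.uint8)
        depth = bit_depth or 8
    elif pil.mode in ("I", "I;16", "I;16B"):
        arr = np.asarray(pil, dtype=np.uint16)
        depth = bit_depth or 16
    else:
        raise UnsupportedFormatError(f"unsupported PNG mode {pil.mode!r} in {path}")
    return RadiographImage(arr, bit_depth=depth, source_id=source_id)


def write_mask_png(mask: LungMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    PILImage.fromarray(mask.to_uint8(), mode="L").save(path)
    return path


def read_mask_png(path) -> LungMask:
    arr = np.asarray(PILImage.open(path).convert("L"))
    return LungMask(arr > 127)


def read_dicom_as_png(path, size: int = 512) -> RadiographImage:
    """Read a single-frame grayscale DICOM and convert to an 8-bit image.

    Rescale slope/intercept are applied, MONOCHROME1 data is inverted so
    that air is dark, the result is min-max windowed to 8 bits and
    bilinearly resized to ``size`` x ``size`` (the conventional preparation
    of DICOM radiographs for PNG-based training corpora).
    """
    import pydicom
    from skimage.transform import resize as sk_resize

    ds = pydicom.dcmread(str(path))
    frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if frames > 1:
        raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
    if int(getattr(ds, "SamplesPerPixel", 1) or 1) != 1:
        raise UnsupportedFormatError(f"color DICOM not supported: {path}")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    arr = arr * slope + intercept
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        arr = arr.max() - arr
    lo, hi = arr.min(), arr.max()
    arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    arr = sk_resize(arr, (size, size), order=1, mode="reflect", anti_aliasing=False)
    return RadiographImage.from_float(
        arr, bit_depth=8, source_id=str(getattr(ds, "StationName", "") or "dicom")
    )
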