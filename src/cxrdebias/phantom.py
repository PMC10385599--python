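"""Synthetic chest-radiograph phantoms with ground-truth layers.

Every confounder and signal the debiasing pipeline targets is generated as a
separable additive layer so that downstream operators have exact oracles:

* base anatomy — a bright torso ellipse with a smooth vertical intensity
  gradient containing two darker elliptical lung fields (the ground-truth
  mask is the exact rasterized ellipse union);
* ribs — additive raised-cosine bands along gently curved paths clipped to
  the torso;
* nodules — truncated 2-D Gaussian bright blobs centered on lung-field
  pixels;
* a corner projection-label marker whose presence is correlated with the
  class label (the shortcut-learning confounder);
* per-site brightness/contrast/gamma calibration offsets;
* an adjustable fraction of emitted-nodule images that actually contain no
  nodule (planted label noise for the pruning algorithm to recover).

Intensities are composed in normalized [0, 1] floats and quantized to 8 bits
on disk.  Pixel coordinates are 0-based (row, column) with the origin at the
top-left.  One RNG stream per dataset is split per-sample by counter so any
sample can be regenerated in isolation.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, InvalidProfileError, InvalidSpecError
from .image import RadiographImage
from .io_utils import write_mask_png, write_png
from .manifest import LABEL_NODULE, LABEL_NORMAL, MANIFEST_COLUMNS, Manifest
from .segmask import LungMask


class SiteProfile(NamedTuple):
    """Acquisition-site calibration: ``out = in**gamma * gain + offset``."""

    brightness_offset: float
    contrast_gain: float
    gamma: float


IDENTITY_PROFILE = SiteProfile(0.0, 1.0, 1.0)


@dataclass(frozen=True)
class Ellipse:
    """Rotated ellipse in pixel units: center (row, col), semi-axes, radians."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    rotation: float = 0.0

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        cos_t, sin_t = np.cos(self.rotation), np.sin(self.rotation)
        u = cos_t * dr + sin_t * dc
        v = -sin_t * dr + cos_t * dc
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def half_extents(self) -> Tuple[float, float]:
        a, b = self.semi_axes
        cos_t, sin_t = np.cos(self.rotation), np.sin(self.rotation)
        er = np.sqrt((a * cos_t) ** 2 + (b * sin_t) ** 2)
        ec = np.sqrt((a * sin_t) ** 2 + (b * cos_t) ** 2)
        return float(er), float(ec)


def _default_lungs(size: int = 256) -> Tuple[Ellipse, Ellipse]:
    s = size / 256.0
    return (
        Ellipse((138 * s, 82 * s), (62 * s, 34 * s), rotation=0.10),
        Ellipse((138 * s, 174 * s), (62 * s, 34 * s), rotation=-0.10),
    )


# Marker block geometry (rows, cols), top-left corner, per the projection
# labels stamped onto real radiographs.
MARKER_ROWS = (6, 18)
MARKER_COLS = (6, 30)
MARKER_INTENSITY = 0.35


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic radiograph generator.

    The defaults describe the study conditions used throughout the test
    suite: a 256-pixel field of view, two slightly rotated lung ellipses,
    seven ribs of moderate amplitude, a 16-pixel nodule at 0.30 contrast,
    no marker confounder, a single identity acquisition site and no label
    noise.  Experiments enable the confounders explicitly.
    """

    image_size: int = 256
    lung_ellipses: Optional[Tuple[Ellipse, Ellipse]] = None  # default: scaled
    rib_count: int = 7
    rib_amplitude: float = 0.12
    rib_period: float = 26.0
    nodule_diameter_px: int = 16
    nodule_contrast: float = 0.30
    marker_enabled: bool = False
    marker_class_correlation: float = 1.0
    site_profiles: Tuple[SiteProfile, ...] = (IDENTITY_PROFILE,)
    mislabel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise InvalidSpecError("image_size must be >= 32")
        if self.lung_ellipses is None:
            object.__setattr__(self, "lung_ellipses", _default_lungs(self.image_size))
        if len(self.lung_ellipses) != 2:
            raise InvalidSpecError("exactly two lung ellipses are required")
        for ell in self.lung_ellipses:
            er, ec = ell.half_extents()
            cr, cc = ell.center
            if (
                cr - er < 0
                or cr + er > self.image_size - 1
                or cc - ec < 0
                or cc + ec > self.image_size - 1
            ):
                raise InvalidSpecError(
                    f"lung ellipse {ell} extends outside the image bounds"
                )
        for name in ("rib_amplitude", "nodule_contrast"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.marker_class_correlation <= 1.0):
            raise InvalidSpecError("marker_class_correlation must be in [0, 1]")
        if not (0.0 <= self.mislabel_fraction < 1.0):
            raise InvalidSpecError("mislabel_fraction must be in [0, 1)")
        min_semi = min(min(e.semi_axes) for e in self.lung_ellipses)
        if self.nodule_diameter_px > min_semi:
            raise InvalidSpecError(
                f"nodule_diameter_px={self.nodule_diameter_px} exceeds the "
                f"smaller lung semi-axis ({min_semi:.1f})"
            )
        profiles = tuple(SiteProfile(*p) for p in self.site_profiles)
        for p in profiles:
            if p.gamma <= 0:
                raise InvalidProfileError(f"gamma must be positive, got {p.gamma}")
        object.__setattr__(self, "site_profiles", profiles)
        object.__setattr__(self, "lung_ellipses", tuple(self.lung_ellipses))

    def true_mask(self) -> LungMask:
        """Rasterized union of the two lung ellipses (pixel-center test)."""
        rows = np.arange(self.image_size, dtype=np.float64)[:, None]
        cols = np.arange(self.image_size, dtype=np.float64)[None, :]
        union = np.zeros((self.image_size, self.image_size), dtype=bool)
        for ell in self.lung_ellipses:
            union |= ell.contains(rows, cols)
        return LungMask(union)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["lung_ellipses"] = [
            {"center": list(e.center), "semi_axes": list(e.semi_axes), "rotation": e.rotation}
            for e in self.lung_ellipses
        ]
        d["site_profiles"] = [list(p) for p in self.site_profiles]
        return json.dumps(d, indent=2)


@dataclass
class PhantomSample:
    """A generated phantom with its ground-truth layers.

    ``image`` equals ``clip(base_layer + rib_layer + nodule_layer +
    marker_layer, 0, 1)`` quantized to 8 bits; the stored float layers are
    the oracles for the suppression and debiasing operators.
    """

    image: RadiographImage
    true_mask: LungMask
    base_layer: np.ndarray
    rib_layer: np.ndarray
    nodule_layer: np.ndarray
    marker_layer: np.ndarray
    nodule_centers: List[Tuple[int, int]]
    true_label: str
    emitted_label: str
    site_id: int

    @property
    def mislabeled(self) -> bool:
        return self.true_label != self.emitted_label

    def image_float(self) -> np.ndarray:
        return self.image.to_float()

    def composed_float(self) -> np.ndarray:
        """Recompose the image from its stored layers (pre-quantization)."""
        return np.clip(
            self.base_layer + self.rib_layer + self.nodule_layer + self.marker_layer,
            0.0,
            1.0,
        )

    def rib_free_float(self) -> np.ndarray:
        """The rib-free twin of this phantom (suppression target)."""
        return np.clip(
            self.base_layer + self.nodule_layer + self.marker_layer, 0.0, 1.0
        )


def apply_site_bias(image: RadiographImage, profile: SiteProfile) -> RadiographImage:
    """Apply an acquisition-site calibration profile to a radiograph.

    ``out = clip((in / max) ** gamma * gain + offset, 0, 1)`` rescaled back
    to the image's bit depth.  Deterministic; the identity profile
    ``(0, 1, 1)`` leaves the image unchanged.
    """
    profile = SiteProfile(*profile)
    if profile.gamma <= 0:
        raise InvalidProfileError(f"gamma must be positive, got {profile.gamma}")
    out = _bias_float(image.to_float(), profile)
    return RadiographImage.from_float(
        out, bit_depth=image.bit_depth, source_id=image.source_id, label=image.label
    )


def _bias_float(arr: np.ndarray, profile: SiteProfile) -> np.ndarray:
    return np.clip(
        np.power(arr, profile.gamma) * profile.contrast_gain
        + profile.brightness_offset,
        0.0,
        1.0,
    )


def _torso_ellipse(size: int) -> Ellipse:
    return Ellipse((0.53 * size, 0.50 * size), (0.47 * size, 0.44 * size))


def _base_anatomy(spec: PhantomSpec, lung_mask: np.ndarray) -> np.ndarray:
    size = spec.image_size
    rows = np.arange(size, dtype=np.float64)[:, None]
    cols = np.arange(size, dtype=np.float64)[None, :]
    torso = _torso_ellipse(size).contains(rows, cols)
    gradient = 0.80 - 0.28 * (rows / size)
    base = np.where(torso, gradient, 0.04)
    base = np.where(lung_mask, base * 0.42, base)
    return base


def _rib_layer(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    layer = np.zeros((size, size), dtype=np.float64)
    if spec.rib_count == 0 or spec.rib_amplitude == 0.0:
        return layer
    rows = np.arange(size, dtype=np.float64)[:, None]
    cols = np.arange(size, dtype=np.float64)[None, :]
    torso = _torso_ellipse(size).contains(rows, cols)
    lung_top = min(e.center[0] - e.half_extents()[0] for e in spec.lung_ellipses)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    jitter = rng.normal(0.0, 1.5, size=spec.rib_count)
    half_width = 0.30 * spec.rib_period
    droop = 0.045 * size
    wiggle = 0.012 * size
    x = (cols - size / 2.0) / (size / 2.0)
    for i in range(spec.rib_count):
        y0 = lung_top + 0.4 * spec.rib_period + i * spec.rib_period + jitter[i]
        path = (
            y0
            + droop * x**2
            + wiggle * np.sin(2.0 * np.pi * cols / size + phase + 0.4 * i)
        )
        dist = rows - path
        band = np.where(
            np.abs(dist) < half_width,
            spec.rib_amplitude * np.cos(np.pi * dist / (2.0 * half_width)) ** 2,
            0.0,
        )
        layer += band
    layer *= torso
    return layer


def _nodule_layer(
    spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    size = spec.image_size
    radius = spec.nodule_diameter_px / 2.0
    rows = np.arange(size, dtype=np.float64)[:, None]
    cols = np.arange(size, dtype=np.float64)[None, :]
    # nodule centers are sampled only from true-mask foreground pixels far
    # enough from the border for the blob to fit in the image
    rr, cc = np.nonzero(mask)
    fits = (
        (rr >= radius)
        & (rr <= size - 1 - radius)
        & (cc >= radius)
        & (cc <= size - 1 - radius)
    )
    rr, cc = rr[fits], cc[fits]
    if len(rr) == 0:
        raise InvalidSpecError("no lung-field pixel can host the nodule blob")
    idx = int(rng.integers(len(rr)))
    center = (int(rr[idx]), int(cc[idx]))
    sigma = spec.nodule_diameter_px / 4.0
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    blob = spec.nodule_contrast * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > radius**2] = 0.0  # truncate at the stated diameter
    return blob, [center]


def sample_rng(spec: PhantomSpec, index: int) -> np.random.Generator:
    """Per-sample RNG split from the dataset stream by counter."""
    return np.random.default_rng(np.random.SeedSequence((spec.seed, index)))


def generate_sample(
    spec: PhantomSpec,
    label: str,
    rng,
    emitted_label: Optional[str] = None,
    site_index: int = 0,
) -> PhantomSample:
    """Generate one phantom radiograph.

    ``label`` is the ground-truth content label; ``emitted_label`` (default:
    same) is the label the manifest will carry and the one the corner-marker
    confounder correlates with.  ``rng`` is a numpy Generator or an integer
    seed; generation is deterministic given ``(spec, label, rng state)``.
    """
    if label not in (LABEL_NODULE, LABEL_NORMAL):
        raise ValueError(f"unknown label {label!r}")
    if emitted_label is None:
        emitted_label = label
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    mask = spec.true_mask()
    profile = spec.site_profiles[site_index % len(spec.site_profiles)]

    base = _bias_float(_base_anatomy(spec, mask.pixels), profile)
    gain = profile.contrast_gain
    rib = gain * _rib_layer(spec, rng)
    if label == LABEL_NODULE:
        nodule, centers = _nodule_layer(spec, mask.pixels, rng)
        nodule = gain * nodule
    else:
        nodule, centers = np.zeros_like(base), []

    marker = np.zeros_like(base)
    marker_draw = rng.random()  # drawn regardless of flags to keep the
    # per-sample stream layout stable across marker settings
    if spec.marker_enabled:
        p = (
            spec.marker_class_correlation
            if emitted_label == LABEL_NODULE
            else 1.0 - spec.marker_class_correlation
        )
        if marker_draw < p:
            marker[MARKER_ROWS[0] : MARKER_ROWS[1], MARKER_COLS[0] : MARKER_COLS[1]] = (
                gain * MARKER_INTENSITY
            )

    composed = np.clip(base + rib + nodule + marker, 0.0, 1.0)
    image = RadiographImage.from_float(
        composed,
        bit_depth=8,
        source_id=f"site{site_index % len(spec.site_profiles)}",
        label=emitted_label,
    )
    return PhantomSample(
        image=image,
        true_mask=mask,
        base_layer=base,
        rib_layer=rib,
        nodule_layer=nodule,
        marker_layer=marker,
        nodule_centers=centers,
        true_label=label,
        emitted_label=emitted_label,
        site_id=site_index % len(spec.site_profiles),
    )


def generate_dataset(
    spec: PhantomSpec,
    n_nodule: int,
    n_normal: int,
    out_dir=None,
) -> Tuple[Manifest, List[PhantomSample]]:
    """Generate a labeled phantom dataset.

    ``n_nodule`` rows carry the emitted nodule label and ``n_normal`` rows
    the non-nodule label.  Exactly ``round(mislabel_fraction * n_nodule)``
    of the emitted-nodule rows are planted mislabels: their true content is
    non-nodule.  Site profiles are assigned round-robin over all rows.  When
    ``out_dir`` is given, 8-bit PNG images and masks, a CSV manifest and a
    JSON sidecar with the full spec are written there.
    """
    if n_nodule < 0 or n_normal < 0:
        raise ValueError("sample counts must be >= 0")
    if n_nodule + n_normal == 0:
        raise EmptyDatasetError("refusing to generate an empty dataset")

    n_mislabeled = int(round(spec.mislabel_fraction * n_nodule))
    flip_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1 << 30)))
    flipped = set(
        int(i) for i in flip_rng.choice(n_nodule, size=n_mislabeled, replace=False)
    ) if n_mislabeled else set()

    samples: List[PhantomSample] = []
    records = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for index in range(n_nodule + n_normal):
        if index < n_nodule:
            emitted = LABEL_NODULE
            true = LABEL_NORMAL if index in flipped else LABEL_NODULE
        else:
            emitted = LABEL_NORMAL
            true = LABEL_NORMAL
        sample = generate_sample(
            spec,
            true,
            sample_rng(spec, index),
            emitted_label=emitted,
            site_index=index,
        )
        samples.append(sample)
        image_id = f"img_{index:04d}"
        image_rel = f"images/{image_id}.png"
        mask_rel = f"masks/{image_id}_mask.png"
        if out_dir is not None:
            write_png(sample.image, out_dir / image_rel)
            write_mask_png(sample.true_mask, out_dir / mask_rel)
        records.append(
            {
                "image_id": image_id,
                "image_path": image_rel,
                "mask_path": mask_rel,
                "emitted_label": emitted,
                "true_label": true,
                "patient_id": f"p{index:04d}",
                "site_id": sample.site_id,
                "mislabeled": emitted != true,
            }
        )

    df = pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS)
    manifest = Manifest(df, root=out_dir)
    if out_dir is not None:
        manifest.write(out_dir / "manifest.csv")
        (out_dir / "phantom_spec.json").write_text(spec.to_json())
    return manifest, samples
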