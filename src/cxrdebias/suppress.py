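"""Learned rib suppression.

Ribs appear as thin, horizontally extended bright bands whose prominence
varies between repositories, making them a confounding variable for nodule
classifiers.  The suppressor estimates the additive rib component with a
bank of directional morphological top-hat features — a vertical grey-scale
opening removes bright structures that are vertically thin (rib bands), and
a horizontal opening of that residue keeps only structures that are also
horizontally long, which spares compact bright features such as nodules and
corner projection labels — and subtracts a trained linear combination of
those feature maps from the image.  The combination weights are trained by
full-batch gradient descent with a mean-squared-error objective on
(rib image, rib-free image) pairs.

The operator slot is pluggable: anything exposing ``apply(float_image)``
can stand in for the default model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyTrainingSetError, ShapeMismatchError
from .image import RadiographImage

#: vertical structuring-element lengths (pixels): bright structures thinner
#: than these are candidate rib bands
DEFAULT_VERTICAL_LENGTHS = (12, 18, 24, 32)
#: horizontal opening width: rib candidates narrower than this are treated
#: as compact features (nodules, markers) and spared
DEFAULT_HORIZONTAL_WIDTH = 31


def rib_feature_maps(
    img: np.ndarray,
    vertical_lengths: Sequence[int] = DEFAULT_VERTICAL_LENGTHS,
    horizontal_width: int = DEFAULT_HORIZONTAL_WIDTH,
) -> np.ndarray:
    """Directional top-hat feature stack, shape (n_features + 1, H, W).

    The last channel is a constant-one bias plane.
    """
    img = np.asarray(img, dtype=np.float64)
    feats = []
    for length in vertical_lengths:
        tophat = img - ndi.grey_opening(img, size=(int(length), 1), mode="reflect")
        tophat = ndi.grey_opening(tophat, size=(1, int(horizontal_width)), mode="reflect")
        feats.append(tophat)
    feats.append(np.ones_like(img))
    return np.stack(feats)


@dataclass
class SuppressorModel:
    """A trained rib-suppression transform.

    ``weights`` combine the top-hat feature maps into a rib-layer estimate
    that is subtracted from the input; training metadata (epochs, seed and
    the per-epoch loss curve) is kept for reproducibility audits.
    """

    weights: np.ndarray
    vertical_lengths: Tuple[int, ...] = DEFAULT_VERTICAL_LENGTHS
    horizontal_width: int = DEFAULT_HORIZONTAL_WIDTH
    loss_curve: List[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0
    learning_rate: float = 0.0

    def rib_estimate(self, img: np.ndarray) -> np.ndarray:
        feats = rib_feature_maps(img, self.vertical_lengths, self.horizontal_width)
        return np.tensordot(self.weights, feats, axes=1)

    def apply(self, img: np.ndarray) -> np.ndarray:
        """Suppress ribs in a normalized [0, 1] float image (shape preserved)."""
        return np.clip(np.asarray(img, dtype=np.float64) - self.rib_estimate(img), 0.0, 1.0)


def train_suppressor(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    epochs: int = 30,
    seed: int = 0,
    learning_rate: float = 0.2,
    pixels_per_image: int = 3000,
    vertical_lengths: Sequence[int] = DEFAULT_VERTICAL_LENGTHS,
    horizontal_width: int = DEFAULT_HORIZONTAL_WIDTH,
) -> SuppressorModel:
    """Train the suppressor on (rib image, rib-free image) pairs.

    Feature maps are computed once per pair and the combination weights are
    fitted by full-batch gradient descent on a per-pair pixel subsample
    (MSE against the residual ``rib = input - target``).  Deterministic
    given the seed; the recorded training loss decreases monotonically for
    the default learning rate.  On an identity task (input == target) the
    weights shrink toward zero and the model approaches a pass-through.
    """
    if len(pairs) == 0:
        raise EmptyTrainingSetError("suppressor training requires at least one pair")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for x, y in pairs:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if x.shape != y.shape:
            raise ShapeMismatchError("training pair images must share a shape")
        feats = rib_feature_maps(x, vertical_lengths, horizontal_width)
        idx = rng.choice(x.size, size=min(pixels_per_image, x.size), replace=False)
        r, c = np.unravel_index(idx, x.shape)
        xs.append(feats[:, r, c].T)
        ys.append((x - y)[r, c])
    design = np.concatenate(xs)
    target = np.concatenate(ys)

    # standardize all but the bias channel for well-conditioned descent
    mu = design.mean(axis=0)
    sd = np.maximum(design.std(axis=0), 1e-9)
    mu[-1], sd[-1] = 0.0, 1.0
    xstd = (design - mu) / sd

    # small non-zero init so even an already-solved task has loss head-room
    w = np.full(xstd.shape[1], 0.01)
    loss_curve: List[float] = []
    for _ in range(epochs):
        err = xstd @ w - target
        loss_curve.append(float(np.mean(err**2)))
        w = w - learning_rate * 2.0 * (xstd.T @ err) / len(target)

    # fold the standardization back into raw-feature weights
    weights = w / sd
    weights[-1] = w[-1] - float(np.sum(weights[:-1] * mu[:-1]))
    return SuppressorModel(
        weights=weights,
        vertical_lengths=tuple(int(v) for v in vertical_lengths),
        horizontal_width=int(horizontal_width),
        loss_curve=loss_curve,
        epochs=epochs,
        seed=seed,
        learning_rate=learning_rate,
    )


def suppress_ribs(image: RadiographImage, model: SuppressorModel) -> RadiographImage:
    """Apply a trained suppressor to a radiograph (shape and range preserved).

    No label or mask information is consulted.
    """
    out = model.apply(image.to_float())
    return RadiographImage.from_float(
        out, bit_depth=image.bit_depth, source_id=image.source_id, label=image.label
    )


def suppress_batch(
    images: Sequence[RadiographImage], model: SuppressorModel
) -> List[RadiographImage]:
    """Suppress a batch of images, order preserved."""
    return [suppress_ribs(img, model) for img in images]
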