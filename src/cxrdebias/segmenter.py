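"""Trainable lung-field segmenter.

A per-pixel logistic model over local intensity and geometric features,
trained by full-batch gradient descent on pixels subsampled from
(image, gold mask) pairs.  It plays the role of the segmentation network in
the pipeline: any object exposing ``predict_proba_map(image)`` can be
plugged in instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyTrainingSetError
from .image import RadiographImage
from .segmask import LungMask, dice

#: default probability cut; ties at exactly 0.5 map to foreground
DEFAULT_THRESHOLD = 0.5


def _pixel_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack, shape (H*W, n_features)."""
    h, w = img.shape
    g2 = ndi.gaussian_filter(img, 2.0)
    g8 = ndi.gaussian_filter(img, 8.0)
    rows = np.broadcast_to(np.linspace(0.0, 1.0, h)[:, None], (h, w))
    cols = np.broadcast_to(np.linspace(0.0, 1.0, w)[None, :], (h, w))
    feats = [
        img,
        img**2,
        g2,
        g2**2,
        g8,
        g8**2,
        rows,
        cols,
        (rows - 0.5) ** 2,
        (cols - 0.5) ** 2,
        np.abs(cols - 0.5),
    ]
    return np.stack([f.ravel() for f in feats], axis=1)


@dataclass
class SegmenterModel:
    """Trained per-pixel lung-field model with its validation Dice curve."""

    weights: np.ndarray
    bias: float
    mean: np.ndarray
    std: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    dice_curve: List[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0

    def predict_proba_map(self, image: RadiographImage) -> np.ndarray:
        img = image.to_float()
        x = (_pixel_features(img) - self.mean) / self.std
        z = x @ self.weights + self.bias
        return (1.0 / (1.0 + np.exp(-z))).reshape(img.shape)


def train_segmenter(
    pairs: Sequence[Tuple[RadiographImage, LungMask]],
    epochs: int = 20,
    seed: int = 0,
    learning_rate: float = 4.0,
    pixels_per_image: int = 2000,
    val_fraction: float = 0.2,
) -> SegmenterModel:
    """Train the segmenter on (image, gold mask) pairs.

    Deterministic given the seed.  The last ``val_fraction`` of the pairs is
    held out; the per-epoch validation Dice curve is stored on the model.
    """
    if len(pairs) == 0:
        raise EmptyTrainingSetError("segmenter training requires at least one pair")
    n_val = max(1, int(round(val_fraction * len(pairs)))) if len(pairs) > 1 else 0
    train_pairs = pairs[: len(pairs) - n_val] if n_val else list(pairs)
    val_pairs = pairs[len(pairs) - n_val :] if n_val else []

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for image, mask in train_pairs:
        feats = _pixel_features(image.to_float())
        labels = mask.pixels.ravel().astype(np.float64)
        idx = rng.choice(feats.shape[0], size=min(pixels_per_image, feats.shape[0]), replace=False)
        xs.append(feats[idx])
        ys.append(labels[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    mean = x.mean(axis=0)
    std = np.maximum(x.std(axis=0), 1e-6)
    x = (x - mean) / std

    w = np.zeros(x.shape[1])
    b = 0.0
    model = SegmenterModel(w, b, mean, std, epochs=epochs, seed=seed)
    dice_curve: List[float] = []
    for _epoch in range(epochs):
        z = x @ w + b
        p = 1.0 / (1.0 + np.exp(-z))
        grad_z = (p - y) / len(y)
        w = w - learning_rate * (x.T @ grad_z + 1e-4 * w)
        b = b - learning_rate * float(grad_z.sum())
        if val_pairs:
            model.weights, model.bias = w, b
            scores = [
                dice(predict_mask(model, img), gold) for img, gold in val_pairs
            ]
            dice_curve.append(float(np.mean(scores)))
    model.weights, model.bias = w, b
    model.dice_curve = dice_curve
    return model


def predict_mask(model: SegmenterModel, image: RadiographImage) -> LungMask:
    """Thresholded probability map; raw (unrepaired) mask.

    Ties at exactly the threshold map to foreground.
    """
    proba = model.predict_proba_map(image)
    return LungMask(proba >= model.threshold)
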