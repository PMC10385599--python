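"""Pluggable binary nodule classifiers.

The default ``tiny_cnn`` architecture is a fixed convolutional feature
extractor (multi-scale Laplacian-of-Gaussian blob responses max-pooled over
a coarse grid, plus mean-pooled intensities) feeding a logistic head trained
by full-batch gradient descent with binary cross-entropy loss.  Training
follows the two-phase schedule used for the fold models: base epochs at the
base learning rate, then fine-tuning epochs at a lower rate, with the
weights checkpointed at minimum validation loss across both phases.

The blob features give the head coarse translation tolerance for nodules;
the mean-pooled intensities deliberately expose corner markers and
brightness offsets, so an undebiased training set lets the model learn the
confounder shortcut — exactly the failure mode the pipeline is meant to
remove.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as sk_resize


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the fold/master classifier.

    The 50 + 10 epoch schedule with a reduced fine-tuning rate and
    minimum-validation-loss checkpointing mirrors standard two-phase
    transfer-learning practice; the learning rates are scaled for the
    full-batch logistic head.
    """

    architecture: str = "tiny_cnn"
    learning_rate: float = 0.1
    epochs: int = 50
    fine_tune_epochs: int = 10
    fine_tune_learning_rate: float = 0.01
    batch_size: Optional[int] = None
    seed: int = 0
    decision_threshold: float = 0.5
    input_size: int = 96
    l2: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.fine_tune_epochs < 0:
            raise ValueError("fine_tune_epochs must be >= 0")
        if self.learning_rate <= 0 or self.fine_tune_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must be in (0, 1)")


#: LoG scales (pixels at input_size resolution) for blob responses
BLOB_SIGMAS = (1.5, 2.5)
#: pooling grid (POOL_GRID x POOL_GRID cells)
POOL_GRID = 4
#: neighborhood (pixels) that must be free of zeroed background for a blob
#: response to count — keeps segmentation-mask borders out of the max-pool
VALID_EROSION = 9


def _pool(arr: np.ndarray, grid: int, op) -> np.ndarray:
    h, w = arr.shape
    hs, ws = h // grid, w // grid
    view = arr[: hs * grid, : ws * grid].reshape(grid, hs, grid, ws)
    return op(op(view, axis=3), axis=1).ravel()


def extract_features(images: Sequence[np.ndarray], input_size: int = 96) -> np.ndarray:
    """Feature matrix for a batch of normalized [0, 1] float images.

    Images of any shape are bilinearly resized to ``input_size`` squared
    before feature extraction, so cropped and uncropped inputs share a
    feature space.  Blob responses are zeroed where the local neighborhood
    touches (near-)zero background, so the sharp lung-mask boundary of
    segmented images does not drown genuine blobs; the validity region is
    derived from the image alone, never from a mask or label.
    """
    rows = []
    for img in images:
        img = np.asarray(img, dtype=np.float64)
        if img.shape != (input_size, input_size):
            img = sk_resize(
                img, (input_size, input_size), order=1, mode="reflect",
                anti_aliasing=True,
            )
        valid = ndi.binary_erosion(
            img > 0.02, structure=np.ones((VALID_EROSION, VALID_EROSION))
        )
        feats = []
        for sigma in BLOB_SIGMAS:
            response = -ndi.gaussian_laplace(img, sigma) * sigma**2
            feats.append(_pool(np.where(valid, response, 0.0), POOL_GRID, np.max))
        feats.append(_pool(img, POOL_GRID, np.mean))
        feats.append(
            np.array([img.mean(), img.std(), img.max(), np.quantile(img, 0.99)])
        )
        rows.append(np.concatenate(feats))
    return np.asarray(rows)


@dataclass
class TinyCxrClassifier:
    """Logistic head over fixed blob/pooling features."""

    spec: ClassifierSpec
    weights: Optional[np.ndarray] = None
    bias: float = 0.0
    mean: Optional[np.ndarray] = None
    std: Optional[np.ndarray] = None
    loss_curve: List[float] = field(default_factory=list)
    val_loss_curve: List[float] = field(default_factory=list)

    def featurize(self, images: Sequence[np.ndarray]) -> np.ndarray:
        return extract_features(images, input_size=self.spec.input_size)

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
    ) -> "TinyCxrClassifier":
        """Two-phase full-batch gradient descent with BCE loss.

        When a validation set is supplied, the returned weights are the
        checkpoint with minimum validation loss across base and fine-tune
        epochs (otherwise the final weights).  Deterministic given the spec.
        """
        spec = self.spec
        self.mean = x.mean(axis=0)
        self.std = np.maximum(x.std(axis=0), 1e-6)
        xs = (x - self.mean) / self.std
        xvs = (x_val - self.mean) / self.std if x_val is not None else None
        y = np.asarray(y, dtype=np.float64)

        w = np.zeros(xs.shape[1])
        b = 0.0
        best = (np.inf, w.copy(), b)
        self.loss_curve, self.val_loss_curve = [], []

        # full-batch Adam; deterministic (zero init, no shuffling)
        mw = np.zeros_like(w)
        vw = np.zeros_like(w)
        mb = vb = 0.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        schedule = [(spec.learning_rate, spec.epochs)]
        if spec.fine_tune_epochs:
            schedule.append((spec.fine_tune_learning_rate, spec.fine_tune_epochs))
        for lr, n_epochs in schedule:
            for _ in range(n_epochs):
                z = xs @ w + b
                p = 1.0 / (1.0 + np.exp(-z))
                self.loss_curve.append(self._bce(p, y))
                grad_z = (p - y) / len(y)
                gw = xs.T @ grad_z + spec.l2 * w
                gb = float(grad_z.sum())
                step += 1
                mw = beta1 * mw + (1 - beta1) * gw
                vw = beta2 * vw + (1 - beta2) * gw**2
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb**2
                w = w - lr * (mw / (1 - beta1**step)) / (
                    np.sqrt(vw / (1 - beta2**step)) + eps
                )
                b = b - lr * (mb / (1 - beta1**step)) / (
                    np.sqrt(vb / (1 - beta2**step)) + eps
                )
                if xvs is not None:
                    pv = 1.0 / (1.0 + np.exp(-(xvs @ w + b)))
                    val_loss = self._bce(pv, np.asarray(y_val, dtype=np.float64))
                    self.val_loss_curve.append(val_loss)
                    if val_loss < best[0]:
                        best = (val_loss, w.copy(), b)
        if xvs is not None and np.isfinite(best[0]):
            _, w, b = best
        self.weights, self.bias = w, b
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("classifier is not fitted")
        xs = (x - self.mean) / self.std
        return 1.0 / (1.0 + np.exp(-(xs @ self.weights + self.bias)))


#: registry of available architectures; users may add their own entries
CLASSIFIERS: Dict[str, type] = {"tiny_cnn": TinyCxrClassifier}


def build_classifier(spec: ClassifierSpec) -> TinyCxrClassifier:
    try:
        cls = CLASSIFIERS[spec.architecture]
    except KeyError:
        raise ValueError(
            f"unknown classifier architecture {spec.architecture!r}; "
            f"available: {sorted(CLASSIFIERS)}"
        )
    return cls(spec)
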