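"""Ablation grid over the debiasing operators.

Six experiment configurations (A–F) toggle lung-field segmentation, close
cropping, and rib suppression over the canonical pipeline (equalization is
always applied); cropping is only ever combined with segmentation.  Each
experiment preprocesses the corpus, runs the evolutionary pruning loop to
class balance, trains a master model on the balanced manifest, and can then
be evaluated on an external positives-only corpus processed with the
byte-identical pipeline configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classifier import ClassifierSpec, TinyCxrClassifier, build_classifier
from .errors import EmptyDatasetError
from .image import RadiographImage
from .manifest import Manifest
from .preprocess import PipelineFlags, run_image_pipeline
from .prune import FeatureTable, PruneLedger, pruning_loop, stable_auc_round
from .segmask import LungMask, QC_PASS, qc_mask, repair_mask
from .suppress import SuppressorModel, train_suppressor

#: Table of the six ablation experiments:
#: (segmentation, cropping, rib suppression)
GRID_FLAGS = {
    "A": (False, False, False),
    "B": (False, False, True),
    "C": (True, False, False),
    "D": (True, False, True),
    "E": (True, True, False),
    "F": (True, True, True),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One row of the ablation grid."""

    experiment_id: str
    segmentation: bool
    cropping: bool
    rib_suppression: bool
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.cropping and not self.segmentation:
            raise ValueError(
                "cropping is only applied in combination with segmentation"
            )

    def flags(self) -> PipelineFlags:
        return PipelineFlags(
            segmentation=self.segmentation,
            cropping=self.cropping,
            rib_suppression=self.rib_suppression,
        )

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()


def expand_grid(
    classifier: Optional[ClassifierSpec] = None, k: int = 4, seed: int = 0
) -> List[ExperimentConfig]:
    """The six ablation configurations A–F."""
    classifier = classifier or ClassifierSpec()
    return [
        ExperimentConfig(
            experiment_id=exp_id,
            segmentation=seg,
            cropping=crop,
            rib_suppression=sup,
            classifier=classifier,
            k=k,
            seed=seed,
        )
        for exp_id, (seg, crop, sup) in GRID_FLAGS.items()
    ]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    ledger: PruneLedger
    master_model: TinyCxrClassifier
    suppressor: Optional[SuppressorModel]
    manifest: Manifest
    qc_excluded: List[str]
    processed: Dict[str, np.ndarray]

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def rounds_to_target(self, target: float = 0.80, window: int = 3) -> Optional[int]:
        if not self.ledger.rounds:
            return 0
        return stable_auc_round(self.ledger, target=target, window=window)


@dataclass
class ExternalReport:
    """Per-image nodule probabilities on a positives-only external corpus."""

    probabilities: pd.DataFrame  # columns: image_id, probability
    accuracy: float
    threshold: float
    config_hash: str
    qc_excluded: List[str]

    def write_scatter(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.probabilities.to_csv(path, index=False)
        return path


def preprocess_corpus(
    config: ExperimentConfig,
    manifest: Manifest,
    images: Mapping[str, RadiographImage],
    masks: Optional[Mapping[str, LungMask]] = None,
    suppressor: Optional[SuppressorModel] = None,
) -> Tuple[Dict[str, np.ndarray], List[str]]:
    """Apply the configured pipeline to every active image.

    When segmentation is enabled, masks are repaired and quality-controlled
    first; images whose masks fail QC are excluded (returned as the second
    element) rather than processed.  Returns normalized float images.
    """
    flags = config.flags()
    if flags.rib_suppression and suppressor is None:
        raise ValueError("config enables rib suppression but no suppressor given")
    if flags.segmentation and masks is None:
        raise ValueError("config enables segmentation but no masks given")
    processed: Dict[str, np.ndarray] = {}
    excluded: List[str] = []
    for image_id in manifest.active_ids():
        mask = None
        if flags.segmentation:
            mask = repair_mask(masks[image_id])
            if qc_mask(mask) != QC_PASS:
                excluded.append(image_id)
                continue
        out = run_image_pipeline(
            images[image_id], flags, mask=mask, suppressor=suppressor
        )
        processed[image_id] = out.to_float()
    return processed, excluded


def train_master_model(
    config: ExperimentConfig,
    manifest: Manifest,
    features: FeatureTable,
    val_fraction: float = 0.2,
) -> TinyCxrClassifier:
    """Train one model on all active (balanced) images.

    A stratified ``val_fraction`` holdout is used only to checkpoint the
    weights at minimum validation loss, mirroring the fold-model protocol.
    """
    ids = manifest.active_ids()
    x, y = features.subset(ids)
    idx = np.arange(len(ids))
    tr, va = train_test_split(
        idx,
        test_size=val_fraction,
        stratify=y,
        random_state=int(config.seed) % (2**31),
    )
    model = build_classifier(config.classifier)
    model.fit(x[tr], y[tr], x[va], y[va])
    return model


def run_experiment(
    config: ExperimentConfig,
    manifest: Manifest,
    images: Mapping[str, RadiographImage],
    masks: Optional[Mapping[str, LungMask]] = None,
    suppressor: Optional[SuppressorModel] = None,
    max_rounds: Optional[int] = None,
    out_dir=None,
) -> ExperimentResult:
    """Pipeline -> pruning to balance -> master model, fully seeded.

    The input manifest is not modified; the result carries its own working
    copy with QC exclusions dropped and pruned rows deactivated.
    """
    working = manifest.copy()
    processed, excluded = preprocess_corpus(
        config, working, images, masks=masks, suppressor=suppressor
    )
    if excluded:
        working.drop_ids(excluded)
    classifier = build_classifier(config.classifier)
    features = FeatureTable.from_images(classifier, processed, working.labels())
    ledger = pruning_loop(
        working,
        config.classifier,
        features,
        k=config.k,
        seed=config.seed,
        max_rounds=max_rounds,
    )
    master = train_master_model(config, working, features)
    result = ExperimentResult(
        config=config,
        ledger=ledger,
        master_model=master,
        suppressor=suppressor,
        manifest=working,
        qc_excluded=excluded,
        processed=processed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        ledger.to_json(out_dir / f"ledger_{config.experiment_id}.json")
        ledger.to_csv(out_dir / f"ledger_{config.experiment_id}.csv")
        (out_dir / f"config_{config.experiment_id}.sha256").write_text(
            result.config_hash
        )
    return result


def external_inference(
    result: ExperimentResult,
    external_manifest: Manifest,
    external_images: Mapping[str, RadiographImage],
    external_masks: Optional[Mapping[str, LungMask]] = None,
    threshold: float = 0.5,
    scatter_path=None,
) -> ExternalReport:
    """Score a positives-only external corpus with a trained master model.

    External images run through the byte-identical pipeline configuration
    (same config hash, same trained suppressor); images failing mask QC are
    excluded before the accuracy computation.  Accuracy is the fraction of
    probabilities above the threshold, all external labels being positive.
    """
    if len(external_manifest.active_ids()) == 0:
        raise EmptyDatasetError("external manifest has no active rows")
    working = external_manifest.copy()
    processed, excluded = preprocess_corpus(
        result.config,
        working,
        external_images,
        masks=external_masks,
        suppressor=result.suppressor,
    )
    if not processed:
        raise EmptyDatasetError("all external images failed mask QC")
    ids = list(processed)
    x = result.master_model.featurize([processed[i] for i in ids])
    proba = result.master_model.predict_proba(x)
    accuracy = float(np.mean(proba > threshold))
    report = ExternalReport(
        probabilities=pd.DataFrame({"image_id": ids, "probability": proba}),
        accuracy=accuracy,
        threshold=threshold,
        config_hash=result.config_hash,
        qc_excluded=excluded,
    )
    if scatter_path is not None:
        report.write_scatter(scatter_path)
    return report


def phantom_suppressor_pairs(
    samples: Sequence,
    segmentation: bool = False,
    cropping: bool = False,
    max_pairs: int = 32,
):
    """(rib, rib-free) pairs in the suppressor's pipeline position.

    The suppressor runs last in the canonical order, so its training input
    is the phantom after equalization (and masking/cropping when the
    configuration enables them) and its target is the same transform of the
    rib-free twin reconstructed from the stored layers.  One crop box,
    computed from the rib image, is applied to both so the pair stays
    aligned.
    """
    from .preprocess import apply_mask, content_bbox, equalize_histogram

    pairs = []
    for s in samples[:max_pairs]:
        x_img = equalize_histogram(s.image)
        y_img = equalize_histogram(RadiographImage.from_float(s.rib_free_float()))
        if segmentation:
            x_img = apply_mask(x_img, s.true_mask)
            y_img = apply_mask(y_img, s.true_mask)
        x, y = x_img.to_float(), y_img.to_float()
        if cropping:
            r0, r1, c0, c1 = content_bbox(x_img.pixels)
            x = x[r0 : r1 + 1, c0 : c1 + 1]
            y = y[r0 : r1 + 1, c0 : c1 + 1]
        pairs.append((x, y))
    return pairs


def train_suppressor_for_config(
    config: ExperimentConfig,
    samples: Sequence,
    epochs: int = 25,
    seed: int = 0,
    max_pairs: int = 32,
) -> SuppressorModel:
    """Train the rib suppressor on pairs matching the config's pipeline."""
    pairs = phantom_suppressor_pairs(
        samples,
        segmentation=config.segmentation,
        cropping=config.cropping,
        max_pairs=max_pairs,
    )
    return train_suppressor(pairs, epochs=epochs, seed=seed)


def train_phantom_suppressor(
    samples: Sequence,
    epochs: int = 30,
    seed: int = 0,
    max_pairs: int = 32,
) -> SuppressorModel:
    """Train a rib suppressor on equalized (uncropped, unmasked) phantoms."""
    pairs = phantom_suppressor_pairs(samples, max_pairs=max_pairs)
    return train_suppressor(pairs, epochs=epochs, seed=seed)


def summarize(
    results: Sequence[ExperimentResult],
    reports: Optional[Mapping[str, ExternalReport]] = None,
    target_auc: float = 0.80,
) -> pd.DataFrame:
    """Summary table: experiment, AUC at balance, rounds to target, external accuracy."""
    rows = []
    for res in results:
        exp = res.config.experiment_id
        rows.append(
            {
                "experiment": exp,
                "auc_at_balance": res.ledger.final_mean_auc,
                "rounds_to_target": res.rounds_to_target(target=target_auc),
                "external_accuracy": (
                    reports[exp].accuracy if reports and exp in reports else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
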