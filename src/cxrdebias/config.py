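"""Run configuration and the end-to-end pipeline runner."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import pandas as pd
import yaml

from .ablation import (
    ExperimentConfig,
    external_inference,
    GRID_FLAGS,
    run_experiment,
    summarize,
    train_suppressor_for_config,
)
from .classifier import ClassifierSpec
from .phantom import PhantomSpec, SiteProfile, generate_dataset

logger = logging.getLogger("cxrdebias")


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end phantom run needs.

    Every parameter has a default; a serialized config reloads to an equal
    value.  All randomness in the run flows from ``seed``.
    """

    out_dir: str = "cxrdebias_run"
    seed: int = 0
    log_level: str = "INFO"
    # phantom study conditions
    n_nodule_train: int = 40
    n_normal_train: int = 32
    n_external: int = 16
    marker_class_correlation: float = 1.0
    mislabel_fraction: float = 0.0
    # experiments to run (subset of A..F)
    experiments: List[str] = field(default_factory=lambda: ["A", "F"])
    k: int = 4
    # classifier hyperparameters
    learning_rate: float = 0.2
    epochs: int = 50
    fine_tune_epochs: int = 10
    fine_tune_learning_rate: float = 0.02
    suppressor_epochs: int = 25
    target_auc: float = 0.80

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            fine_tune_epochs=self.fine_tune_epochs,
            fine_tune_learning_rate=self.fine_tune_learning_rate,
            seed=self.seed,
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        text = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


def training_phantom_spec(config: RunConfig) -> PhantomSpec:
    """The biased training corpus: marker confounder plus two site profiles."""
    return PhantomSpec(
        marker_enabled=True,
        marker_class_correlation=config.marker_class_correlation,
        site_profiles=(
            SiteProfile(-0.04, 0.95, 1.10),
            SiteProfile(0.05, 1.08, 0.90),
        ),
        mislabel_fraction=config.mislabel_fraction,
        seed=config.seed,
    )


def external_phantom_spec(config: RunConfig) -> PhantomSpec:
    """The external corpus: unseen site calibration, no corner markers."""
    return PhantomSpec(
        marker_enabled=False,
        site_profiles=(SiteProfile(0.08, 1.15, 0.85),),
        seed=config.seed + 500,
    )


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Full phantom -> preprocess -> prune -> ablate -> external-test run.

    Writes, under ``config.out_dir``: the generated datasets, per-experiment
    ledgers (JSON + CSV) and scatter CSVs, a ``summary.csv`` table, the
    serialized config and its hash.  Returns the summary table.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    (out_dir / "config.sha256").write_text(config.config_hash())

    unknown = [e for e in config.experiments if e not in GRID_FLAGS]
    if unknown:
        raise ValueError(f"unknown experiment ids: {unknown}")

    logger.info(
        "generating phantom corpora: %d nodule + %d non-nodule train, %d external",
        config.n_nodule_train,
        config.n_normal_train,
        config.n_external,
    )
    train_manifest, train_samples = generate_dataset(
        training_phantom_spec(config),
        config.n_nodule_train,
        config.n_normal_train,
        out_dir=out_dir / "train",
    )
    ext_manifest, ext_samples = generate_dataset(
        external_phantom_spec(config),
        config.n_external,
        0,
        out_dir=out_dir / "external",
    )

    train_images = {i: s.image for i, s in zip(train_manifest.image_ids, train_samples)}
    train_masks = {i: s.true_mask for i, s in zip(train_manifest.image_ids, train_samples)}
    ext_images = {i: s.image for i, s in zip(ext_manifest.image_ids, ext_samples)}
    ext_masks = {i: s.true_mask for i, s in zip(ext_manifest.image_ids, ext_samples)}

    results, reports = [], {}
    for exp_id in config.experiments:
        seg, crop, sup = GRID_FLAGS[exp_id]
        exp = ExperimentConfig(
            experiment_id=exp_id,
            segmentation=seg,
            cropping=crop,
            rib_suppression=sup,
            classifier=config.classifier_spec(),
            k=config.k,
            seed=config.seed,
        )
        suppressor = None
        if sup:
            logger.info("experiment %s: training rib suppressor", exp_id)
            suppressor = train_suppressor_for_config(
                exp,
                train_samples,
                epochs=config.suppressor_epochs,
                seed=config.seed,
            )
        exp_dir = out_dir / f"experiment_{exp_id}"
        exp_dir.mkdir(parents=True, exist_ok=True)
        logger.info("experiment %s: pruning to class balance", exp_id)
        result = run_experiment(
            exp,
            train_manifest,
            train_images,
            masks=train_masks,
            suppressor=suppressor,
            out_dir=exp_dir,
        )
        logger.info(
            "experiment %s: %d rounds (%s), external inference on %d images",
            exp_id,
            len(result.ledger.rounds),
            result.ledger.stop_reason,
            len(ext_manifest),
        )
        report = external_inference(
            result,
            ext_manifest,
            ext_images,
            external_masks=ext_masks,
            scatter_path=exp_dir / "external_scatter.csv",
        )
        results.append(result)
        reports[exp_id] = report

    summary = summarize(results, reports, target_auc=config.target_auc)
    summary.to_csv(out_dir / "summary.csv", index=False)
    logger.info("run complete; summary written to %s", out_dir / "summary.csv")
    return summary
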