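"""Shared fixtures: phantom corpora and the expensive end-to-end runs.

The debiasing-ordering and mislabel-recovery experiments are session-scoped
because several tests (mechanism tests, invariants) read different aspects
of the same runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set

import pytest
from hypothesis import HealthCheck, settings

from cxrdebias.ablation import (
    ExperimentConfig,
    external_inference,
    preprocess_corpus,
    run_experiment,
    train_suppressor_for_config,
)
from cxrdebias.classifier import ClassifierSpec, build_classifier
from cxrdebias.config import RunConfig, external_phantom_spec, training_phantom_spec
from cxrdebias.phantom import PhantomSpec, generate_dataset
from cxrdebias.prune import (
    FeatureTable,
    PruneLedger,
    inference_matrix,
    pruning_loop,
    stratified_kfold,
    train_fold_models,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

N_SEEDS = 5


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def small_dataset(default_spec):
    """10 nodule + 10 non-nodule phantoms, in memory."""
    return generate_dataset(default_spec, 10, 10)


@dataclass
class RecoveryRun:
    seed: int
    planted: Set[str]
    ledger: PruneLedger
    round0_matrix: "object"  # DataFrame: per-image counts before any pruning


@pytest.fixture(scope="session")
def recovery_runs() -> List[RecoveryRun]:
    """Full-debiasing pruning runs on corpora with planted label noise.

    24 emitted-nodule images of which round(0.15 x 24) = 4 contain no
    nodule, versus 20 non-nodule images; experiment-F pipeline; one run per
    seed.
    """
    runs = []
    for seed in range(N_SEEDS):
        spec = PhantomSpec(seed=seed, mislabel_fraction=0.15)
        manifest, samples = generate_dataset(spec, 24, 20)
        planted = set(manifest.df.loc[manifest.df["mislabeled"], "image_id"])
        images = {i: s.image for i, s in zip(manifest.image_ids, samples)}
        masks = {i: s.true_mask for i, s in zip(manifest.image_ids, samples)}
        config = ExperimentConfig(
            "F", True, True, True, classifier=ClassifierSpec(seed=seed), k=4, seed=seed
        )
        suppressor = train_suppressor_for_config(config, samples, epochs=25, seed=seed)
        processed, _ = preprocess_corpus(
            config, manifest, images, masks=masks, suppressor=suppressor
        )
        features = FeatureTable.from_images(
            build_classifier(config.classifier), processed, manifest.labels()
        )
        folds = stratified_kfold(manifest, k=4, seed=seed)
        models, _ = train_fold_models(manifest, folds, config.classifier, features)
        round0 = inference_matrix(models, manifest, folds, features)
        working = manifest.copy()
        ledger = pruning_loop(working, config.classifier, features, k=4, seed=seed)
        runs.append(
            RecoveryRun(seed=seed, planted=planted, ledger=ledger, round0_matrix=round0)
        )
    return runs


@dataclass
class DebiasRun:
    seed: int
    results: Dict[str, "object"]  # experiment id -> ExperimentResult
    reports: Dict[str, "object"]  # experiment id -> ExternalReport


@pytest.fixture(scope="session")
def debias_runs() -> List[DebiasRun]:
    """Experiments A, D, F trained on a marker/site-biased corpus and
    evaluated on an external positives-only site, one run per seed."""
    flag_table = {"A": (False, False, False), "D": (True, False, True), "F": (True, True, True)}
    runs = []
    for seed in range(N_SEEDS):
        rc = RunConfig(seed=seed)
        train_spec = training_phantom_spec(rc)
        ext_spec = external_phantom_spec(rc)
        tman, tsamp = generate_dataset(train_spec, 36, 30)
        eman, esamp = generate_dataset(ext_spec, 24, 0)
        timgs = {i: s.image for i, s in zip(tman.image_ids, tsamp)}
        tmasks = {i: s.true_mask for i, s in zip(tman.image_ids, tsamp)}
        eimgs = {i: s.image for i, s in zip(eman.image_ids, esamp)}
        emasks = {i: s.true_mask for i, s in zip(eman.image_ids, esamp)}
        results, reports = {}, {}
        for exp_id, (seg, crop, sup) in flag_table.items():
            config = ExperimentConfig(
                exp_id, seg, crop, sup, classifier=ClassifierSpec(seed=seed), k=4, seed=seed
            )
            suppressor = (
                train_suppressor_for_config(config, tsamp, epochs=25, seed=seed)
                if sup
                else None
            )
            result = run_experiment(
                config, tman, timgs, masks=tmasks, suppressor=suppressor
            )
            results[exp_id] = result
            reports[exp_id] = external_inference(
                result, eman, eimgs, external_masks=emasks
            )
        runs.append(DebiasRun(seed=seed, results=results, reports=reports))
    return runs
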