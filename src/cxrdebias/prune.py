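"""Evolutionary pruning of the majority nodule class.

Stratified k-fold models are retrained from scratch each round; after every
round each active nodule image is scored by all k fold models in all k shard
contexts (k x k evaluations per image), and the image with the largest
misclassification count is added to a prune list and ignored from the next
round on.  The loop under-samples the majority nodule class one image per
round until the classes balance, recording per-fold validation AUC as it
goes.  The intent is that planted label noise and uninformative hard samples
accumulate misclassifications fastest and are removed first.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifier import ClassifierSpec, TinyCxrClassifier, build_classifier
from .errors import DegenerateFoldError, PruningError, UndefinedAUCError
from .manifest import LABEL_NODULE, LABEL_NORMAL, Manifest

DEFAULT_TARGET_AUC = 0.80
DEFAULT_STABLE_WINDOW = 3


# ---------------------------------------------------------------------------
# feature plumbing
# ---------------------------------------------------------------------------
@dataclass
class FeatureTable:
    """Precomputed classifier features for a fixed set of images.

    The pruning loop retrains models every round on shrinking subsets of the
    same images, so features are extracted once and indexed by image id.
    """

    ids: List[str]
    x: np.ndarray
    labels: Dict[str, str]

    def __post_init__(self):
        self._index = {i: n for n, i in enumerate(self.ids)}

    @classmethod
    def from_images(
        cls,
        classifier: TinyCxrClassifier,
        images: Mapping[str, np.ndarray],
        labels: Mapping[str, str],
    ) -> "FeatureTable":
        ids = list(images)
        x = classifier.featurize([images[i] for i in ids])
        return cls(ids=ids, x=x, labels=dict(labels))

    def subset(self, ids: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
        rows = [self._index[i] for i in ids]
        y = np.array([1.0 if self.labels[i] == LABEL_NODULE else 0.0 for i in ids])
        return self.x[rows], y


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------
def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based AUC with ties credited 0.5.

    Equals the probability that a uniformly random positive outranks a
    uniformly random negative.  Labels may be 0/1 or the canonical label
    strings.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(
        [1 if lab in (1, True, LABEL_NODULE) else 0 for lab in labels]
    )
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------
def stratified_kfold(manifest: Manifest, k: int = 4, seed: int = 0) -> Dict[str, int]:
    """Assign each active image to one of k stratified folds.

    Per-fold class proportions are within one sample of the global
    proportion.  Deterministic given the seed; ``k=1`` puts every sample in
    fold 0.
    """
    df = manifest.active_df()
    ids = list(df["image_id"])
    labels = list(df["emitted_label"])
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return {i: 0 for i in ids}
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = counts[counts < k].to_dict()
        raise PruningError(f"classes with fewer than k={k} members: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    assignment: Dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


# ---------------------------------------------------------------------------
# fold models
# ---------------------------------------------------------------------------
def train_fold_models(
    manifest: Manifest,
    folds: Mapping[str, int],
    spec: ClassifierSpec,
    features: FeatureTable,
) -> Tuple[List[TinyCxrClassifier], List[float]]:
    """Train one model per fold; fold f validates on fold f.

    Each model is checkpointed at minimum validation loss across the base
    and fine-tuning epochs.  Returns the k models and their per-fold
    validation AUC.
    """
    k = max(folds.values()) + 1
    active = set(manifest.active_ids())
    models: List[TinyCxrClassifier] = []
    val_aucs: List[float] = []
    for f in range(k):
        train_ids = [i for i in features.ids if i in active and folds.get(i) != f]
        val_ids = [i for i in features.ids if i in active and folds.get(i) == f]
        x_tr, y_tr = features.subset(train_ids)
        x_va, y_va = features.subset(val_ids)
        if len(np.unique(y_tr)) < 2 or (len(val_ids) and len(np.unique(y_va)) < 2):
            raise DegenerateFoldError(
                f"fold {f} has a single class in train or validation split"
            )
        model = build_classifier(dataclasses.replace(spec, seed=spec.seed + f))
        model.fit(x_tr, y_tr, x_va if len(val_ids) else None, y_va if len(val_ids) else None)
        models.append(model)
        if len(val_ids):
            val_aucs.append(auc(model.predict_proba(x_va), y_va))
        else:
            val_aucs.append(float("nan"))
    return models, val_aucs


def inference_matrix(
    models: Sequence[TinyCxrClassifier],
    manifest: Manifest,
    folds: Mapping[str, int],
    features: FeatureTable,
    decision_threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every active nodule image with every fold model in every shard.

    Each of the k models is applied to each image once per shard context,
    giving exactly k x k evaluations per image.  A model's score for a fixed
    image does not depend on the shard the image arrives in, so the k model
    scores are computed once and replicated k-fold in the bookkeeping,
    preserving the k x k count semantics.  Misclassification means score
    below the decision threshold; counts therefore lie in [0, k**2].
    """
    k = len(models)
    if k == 0:
        raise PruningError("no fold models supplied")
    nodule_ids = manifest.active_ids(LABEL_NODULE)
    missing = [i for i in nodule_ids if i not in folds]
    if missing:
        raise PruningError(f"active nodule images without fold assignment: {missing[:5]}")
    x, _ = features.subset(nodule_ids)
    scores = np.stack([m.predict_proba(x) for m in models])  # (k, n)
    miscls_per_model = (scores < decision_threshold).sum(axis=0)  # in [0, k]
    return pd.DataFrame(
        {
            "image_id": nodule_ids,
            "misclassification_count": (k * miscls_per_model).astype(int),
            "mean_score": scores.mean(axis=0),
            "n_evaluations": k * k,
        }
    ).set_index("image_id")


def select_prune_candidate(
    counts: Mapping[str, int], scores: Mapping[str, float]
) -> str:
    """The image with the largest misclassification count.

    Ties break by lowest mean nodule score, then lexicographically smallest
    image id, making the choice fully deterministic.
    """
    if not counts:
        raise PruningError("no prune candidates")
    return min(counts, key=lambda i: (-counts[i], scores[i], i))


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------
@dataclass
class RoundRecord:
    round_index: int
    pruned_image_id: str
    misclassification_count: int
    per_fold_auc: List[float]
    mean_auc: float
    auc_sd: float


STOP_CLASS_BALANCE = "class_balance"
STOP_MAX_ROUNDS = "max_rounds"


@dataclass
class PruneLedger:
    """Per-round record of the pruning run."""

    rounds: List[RoundRecord] = field(default_factory=list)
    stop_reason: Optional[str] = None
    k: int = 4
    initial_counts: Dict[str, int] = field(default_factory=dict)
    final_per_fold_auc: Optional[List[float]] = None

    @property
    def prune_list(self) -> List[str]:
        return [r.pruned_image_id for r in self.rounds]

    @property
    def mean_auc_sequence(self) -> List[float]:
        return [r.mean_auc for r in self.rounds]

    @property
    def final_mean_auc(self) -> Optional[float]:
        if self.final_per_fold_auc is None:
            return None
        return float(np.mean(self.final_per_fold_auc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": [r.round_index for r in self.rounds],
                "pruned_id": [r.pruned_image_id for r in self.rounds],
                "misclass_count": [r.misclassification_count for r in self.rounds],
                "mean_auc": [r.mean_auc for r in self.rounds],
                "auc_sd": [r.auc_sd for r in self.rounds],
            }
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path=None):
        payload = {
            "stop_reason": self.stop_reason,
            "k": self.k,
            "initial_counts": self.initial_counts,
            "final_per_fold_auc": self.final_per_fold_auc,
            "rounds": [dataclasses.asdict(r) for r in self.rounds],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            path = Path(path)
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(text)
            return path
        return text


def format_pruned_percent(n_pruned: int, pool_size: int) -> str:
    """Render a pruned-record share the way the ledger reports it (e.g. 3.4%)."""
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    return f"{100.0 * n_pruned / pool_size:.1f}%"


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------
def pruning_loop(
    manifest: Manifest,
    spec: ClassifierSpec,
    features: FeatureTable,
    k: int = 4,
    seed: int = 0,
    max_rounds: Optional[int] = None,
) -> PruneLedger:
    """Run the evolutionary pruning loop until class balance.

    Each round retrains the k fold models from scratch on the active images
    (seed schedule ``spec.seed + round``), builds the k x k inference matrix
    over active nodule images, and prunes exactly one.  Fold assignment is
    fixed at round 0 and reused; pruned images simply drop out.  Stops when
    the classes balance or ``max_rounds`` is reached.  The manifest is
    modified in place (``active`` flags cleared).
    """
    counts = manifest.class_counts()
    if counts[LABEL_NODULE] < counts[LABEL_NORMAL]:
        raise PruningError(
            "pruning under-samples the nodule class; it must not start in the "
            f"minority (got {counts[LABEL_NODULE]} nodule vs "
            f"{counts[LABEL_NORMAL]} non-nodule)"
        )
    folds = stratified_kfold(manifest, k=k, seed=seed)
    manifest.fold_assignment = folds
    ledger = PruneLedger(k=k, initial_counts=dict(counts))

    round_index = 0
    while True:
        counts = manifest.class_counts()
        if counts[LABEL_NODULE] == counts[LABEL_NORMAL]:
            ledger.stop_reason = STOP_CLASS_BALANCE
            break
        if max_rounds is not None and round_index >= max_rounds:
            ledger.stop_reason = STOP_MAX_ROUNDS
            break
        round_spec = dataclasses.replace(spec, seed=spec.seed + round_index)
        models, fold_aucs = train_fold_models(manifest, folds, round_spec, features)
        matrix = inference_matrix(
            models, manifest, folds, features, spec.decision_threshold
        )
        candidate = select_prune_candidate(
            matrix["misclassification_count"].to_dict(),
            matrix["mean_score"].to_dict(),
        )
        manifest.deactivate(candidate)
        ledger.rounds.append(
            RoundRecord(
                round_index=round_index,
                pruned_image_id=candidate,
                misclassification_count=int(
                    matrix.loc[candidate, "misclassification_count"]
                ),
                per_fold_auc=[float(a) for a in fold_aucs],
                mean_auc=float(np.mean(fold_aucs)),
                auc_sd=float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
            )
        )
        round_index += 1

    # one extra evaluation on the final (balanced or truncated) manifest so
    # the AUC at the stopping point is recorded
    try:
        _, final_aucs = train_fold_models(manifest, folds, spec, features)
        ledger.final_per_fold_auc = [float(a) for a in final_aucs]
    except DegenerateFoldError:
        ledger.final_per_fold_auc = None
    return ledger


def stable_auc_round(
    ledger,
    target: float = DEFAULT_TARGET_AUC,
    window: int = DEFAULT_STABLE_WINDOW,
) -> Optional[int]:
    """First round from which mean AUC stays at or above the target.

    Returns the smallest round ``r`` with mean AUC >= target for rounds
    ``r .. r+window-1``; the window is truncated at the ledger end only if
    every remaining round qualifies.  ``None`` if never achieved.
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target must be in (0, 1), got {target}")
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = ledger.mean_auc_sequence if isinstance(ledger, PruneLedger) else list(ledger)
    if not seq:
        raise ValueError("ledger has no rounds")
    n = len(seq)
    for r in range(n):
        vals = seq[r : r + window]
        if all(v >= target for v in vals):
            return r
    return None
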