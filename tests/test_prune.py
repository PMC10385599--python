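"""Evolutionary pruning: folds, AUC, inference matrix, loop bookkeeping."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cxrdebias.classifier import ClassifierSpec, build_classifier
from cxrdebias.errors import PruningError, UndefinedAUCError
from cxrdebias.manifest import LABEL_NODULE, LABEL_NORMAL, Manifest, MANIFEST_COLUMNS
from cxrdebias.phantom import PhantomSpec, generate_dataset
from cxrdebias.preprocess import equalize_histogram
from cxrdebias.prune import (
    FeatureTable,
    auc,
    format_pruned_percent,
    inference_matrix,
    pruning_loop,
    select_prune_candidate,
    stable_auc_round,
    stratified_kfold,
    train_fold_models,
)


def make_manifest(n_nodule, n_normal):
    rows = [
        {
            "image_id": f"img_{i:04d}",
            "image_path": "",
            "mask_path": "",
            "emitted_label": LABEL_NODULE if i < n_nodule else LABEL_NORMAL,
            "true_label": LABEL_NODULE if i < n_nodule else LABEL_NORMAL,
            "patient_id": f"p{i:04d}",
            "site_id": 0,
            "mislabeled": False,
        }
        for i in range(n_nodule + n_normal)
    ]
    return Manifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


@pytest.fixture(scope="module")
def tiny_corpus():
    spec = PhantomSpec(seed=4)
    manifest, samples = generate_dataset(spec, 12, 8)
    images = {
        i: equalize_histogram(s.image).to_float()
        for i, s in zip(manifest.image_ids, samples)
    }
    cspec = ClassifierSpec(seed=4, epochs=10, fine_tune_epochs=2)
    features = FeatureTable.from_images(
        build_classifier(cspec), images, manifest.labels()
    )
    return manifest, cspec, features


class TestStratifiedKfold:
    def test_jsrt_scale_fold_counts(self):
        """154 nodule / 93 non-nodule, k=4: folds hold 38-39 and 23-24."""
        manifest = make_manifest(154, 93)
        folds = stratified_kfold(manifest, k=4, seed=0)
        df = manifest.df
        for f in range(4):
            ids = [i for i, ff in folds.items() if ff == f]
            sub = df[df["image_id"].isin(ids)]
            assert int((sub["emitted_label"] == LABEL_NODULE).sum()) in (38, 39)
            assert int((sub["emitted_label"] == LABEL_NORMAL).sum()) in (23, 24)

    def test_single_fold_takes_everything(self):
        manifest = make_manifest(5, 5)
        folds = stratified_kfold(manifest, k=1, seed=0)
        assert set(folds.values()) == {0}

    def test_determinism(self):
        manifest = make_manifest(20, 12)
        assert stratified_kfold(manifest, 4, 7) == stratified_kfold(manifest, 4, 7)

    def test_small_class_is_rejected(self):
        with pytest.raises(PruningError):
            stratified_kfold(make_manifest(10, 3), k=4, seed=0)


class TestAuc:
    def test_pairwise_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_and_ties(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle_on_random_vectors(self):
        """Rank formula vs brute-force pairwise counting, 200 vectors."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(expected)
            assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


class TestInferenceMatrix:
    @pytest.mark.parametrize("k,expected", [(1, 1), (3, 9), (4, 16)])
    def test_evaluations_per_image_is_k_squared(self, k, expected):
        spec = PhantomSpec(seed=4)
        manifest, samples = generate_dataset(spec, 2 * k, 2 * k)
        images = {
            i: equalize_histogram(s.image).to_float()
            for i, s in zip(manifest.image_ids, samples)
        }
        cspec = ClassifierSpec(seed=0, epochs=2, fine_tune_epochs=0)
        features = FeatureTable.from_images(
            build_classifier(cspec), images, manifest.labels()
        )
        folds = stratified_kfold(manifest, k=k, seed=0)
        if k == 1:  # a single shard: one model trained on everything
            x, y = features.subset(manifest.active_ids())
            models = [build_classifier(cspec).fit(x, y)]
        else:
            models, _ = train_fold_models(manifest, folds, cspec, features)
        matrix = inference_matrix(models, manifest, folds, features)
        assert len(matrix) == 2 * k  # one row per active nodule image
        assert (matrix["n_evaluations"] == expected).all()
        assert matrix["misclassification_count"].between(0, k * k).all()
        assert (matrix["misclassification_count"] % k == 0).all()


class TestSelectPruneCandidate:
    def test_largest_misclassification_count_wins(self):
        assert select_prune_candidate(
            {"a": 3, "b": 7, "c": 5}, {"a": 0.5, "b": 0.5, "c": 0.5}
        ) == "b"

    def test_all_zero_counts_fall_back_to_lowest_mean_score(self):
        assert select_prune_candidate({"a": 0, "b": 0}, {"a": 0.9, "b": 0.8}) == "b"

    def test_count_tie_breaks_by_score_then_id(self):
        assert select_prune_candidate(
            {"b": 7, "c": 7}, {"b": 0.4, "c": 0.2}
        ) == "c"
        assert select_prune_candidate({"b": 7, "c": 7}, {"b": 0.4, "c": 0.4}) == "b"

    def test_empty_candidates_are_rejected(self):
        with pytest.raises(PruningError):
            select_prune_candidate({}, {})


class TestPruningLoop:
    def test_prunes_one_nodule_per_round_until_balance(self, tiny_corpus):
        manifest, cspec, features = tiny_corpus
        working = manifest.copy()
        ledger = pruning_loop(working, cspec, features, k=4, seed=4)
        assert ledger.stop_reason == "class_balance"
        assert len(ledger.rounds) == 4  # 12 - 8
        assert len(set(ledger.prune_list)) == 4
        counts = working.class_counts()
        assert counts[LABEL_NODULE] == counts[LABEL_NORMAL] == 8
        labels = manifest.labels()
        assert all(labels[i] == LABEL_NODULE for i in ledger.prune_list)
        # conservation: round r trains with initial - r nodules
        assert [r.round_index for r in ledger.rounds] == [0, 1, 2, 3]

    def test_already_balanced_runs_zero_rounds(self, tiny_corpus):
        manifest, cspec, features = tiny_corpus
        working = manifest.copy()
        for i in working.active_ids(LABEL_NODULE)[:4]:
            working.deactivate(i)
        ledger = pruning_loop(working, cspec, features, k=2, seed=0)
        assert len(ledger.rounds) == 0
        assert ledger.stop_reason == "class_balance"

    def test_non_nodule_majority_is_rejected(self, tiny_corpus):
        manifest, cspec, features = tiny_corpus
        working = manifest.copy()
        for i in working.active_ids(LABEL_NODULE)[:6]:
            working.deactivate(i)
        with pytest.raises(PruningError):
            pruning_loop(working, cspec, features, k=2, seed=0)

    def test_max_rounds_truncates(self, tiny_corpus):
        manifest, cspec, features = tiny_corpus
        working = manifest.copy()
        ledger = pruning_loop(working, cspec, features, k=4, seed=4, max_rounds=2)
        assert len(ledger.rounds) == 2
        assert ledger.stop_reason == "max_rounds"

    def test_loop_is_deterministic(self, tiny_corpus):
        manifest, cspec, features = tiny_corpus
        a = pruning_loop(manifest.copy(), cspec, features, k=4, seed=4)
        b = pruning_loop(manifest.copy(), cspec, features, k=4, seed=4)
        assert a.prune_list == b.prune_list
        assert a.mean_auc_sequence == b.mean_auc_sequence

    def test_ledger_serialization_round_trip(self, tiny_corpus, tmp_path):
        import json

        manifest, cspec, features = tiny_corpus
        ledger = pruning_loop(manifest.copy(), cspec, features, k=4, seed=4)
        ledger.to_csv(tmp_path / "ledger.csv")
        ledger.to_json(tmp_path / "ledger.json")
        frame = pd.read_csv(tmp_path / "ledger.csv")
        assert list(frame["pruned_id"]) == ledger.prune_list
        payload = json.loads((tmp_path / "ledger.json").read_text())
        assert payload["stop_reason"] == "class_balance"
        assert len(payload["rounds"]) == len(ledger.rounds)


class TestStableAucRound:
    def test_declared_rule_on_example_sequence(self):
        seq = [0.7, 0.81, 0.79, 0.82, 0.83, 0.85]
        assert stable_auc_round(seq, target=0.80, window=3) == 3

    def test_all_rounds_above_target_gives_round_zero(self):
        assert stable_auc_round([0.9, 0.95, 0.9, 0.92], target=0.80) == 0

    def test_never_reaching_target_gives_none(self):
        assert stable_auc_round([0.5, 0.6, 0.7], target=0.80) is None

    def test_truncated_window_requires_all_remaining(self):
        assert stable_auc_round([0.5, 0.85, 0.9], target=0.80, window=3) == 1
        assert stable_auc_round([0.5, 0.85, 0.7], target=0.80, window=3) is None

    def test_invalid_target_is_rejected(self):
        with pytest.raises(ValueError):
            stable_auc_round([0.9], target=1.5)


def test_pruned_percent_formatter_matches_reported_style():
    assert format_pruned_percent(10, 293) == "3.4%"
    assert format_pruned_percent(62, 154) == "40.3%"
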