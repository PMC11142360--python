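"""State prediction: training, metrics, TreeSHAP attributions, pairing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import statefate as sf
from statefate.predictor import (
    MODEL_KINDS,
    scaled_hyperparams,
    training_set_from_screen,
)


@pytest.fixture(scope="module")
def separable_toy():
    """Two classes at opposite binary corners plus small perturbations."""
    rng = np.random.default_rng(2)
    rows, labels = [], []
    for i in range(20):
        a = np.ones(8, dtype=int)
        b = np.zeros(8, dtype=int)
        if i % 3 == 0:  # perturb one non-informative coordinate
            a[7] = 0
            b[7] = 1
        rows.append(a)
        labels.append("MES")
        rows.append(b)
        labels.append("NPC")
    X = pd.DataFrame(rows, columns=[f"n{i}" for i in range(8)])
    y = pd.Series(labels)
    return sf.TrainingSet(features=X, labels=y)


@pytest.fixture(scope="module")
def trained_boosted(study):
    train = study["train"]
    hp = scaled_hyperparams("boosted_trees", len(train.features))
    return sf.train_classifier(train, "boosted_trees", hp, seed=7)


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_separable_toy_fits_perfectly(self, separable_toy, kind):
        hp = scaled_hyperparams(kind, len(separable_toy.features))
        clf = sf.train_classifier(separable_toy, kind, hp, seed=2)
        preds = clf.predict_labels(separable_toy.features)
        assert (preds == separable_toy.labels.to_numpy()).all()

    def test_duplicated_feature_leaves_boosted_predictions_unchanged(self, separable_toy):
        X = separable_toy.features
        X_dup = X.copy()
        X_dup["n0_copy"] = X["n0"]
        t_dup = sf.TrainingSet(features=X_dup, labels=separable_toy.labels)
        clf = sf.train_classifier(separable_toy, "boosted_trees", {"subsample": 1.0}, seed=2)
        clf_dup = sf.train_classifier(t_dup, "boosted_trees", {"subsample": 1.0}, seed=2)
        p1 = clf.predict_labels(X)
        p2 = clf_dup.predict_labels(X_dup)
        assert (p1 == p2).all()

    def test_same_seed_same_predictions(self, study):
        train = study["train"]
        hp = scaled_hyperparams("boosted_trees", len(train.features))
        a = sf.train_classifier(train, "boosted_trees", hp, seed=5)
        b = sf.train_classifier(train, "boosted_trees", hp, seed=5)
        assert (a.predict_labels(train.features) == b.predict_labels(train.features)).all()

    def test_single_class_rejected(self):
        X = pd.DataFrame([[0, 1], [1, 0]], columns=["a", "b"])
        y = pd.Series(["MES", "MES"])
        with pytest.raises(ValueError, match="2 classes"):
            sf.train_classifier(sf.TrainingSet(features=X, labels=y), "knn")

    def test_oversized_mtry_clipped_with_warning(self, separable_toy):
        with pytest.warns(UserWarning, match="clipping"):
            sf.train_classifier(
                separable_toy, "random_forest", {"n_estimators": 20, "max_features": 99}, seed=1
            )

    def test_training_set_rejects_non_binary_features(self):
        X = pd.DataFrame([[0.5, 1], [1, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="binary"):
            sf.TrainingSet(features=X, labels=pd.Series(["A", "B"]))


class TestTrainingSetFromScreen:
    def test_labels_are_outcome_classifications(self, study):
        train = training_set_from_screen(study["screen"], study["steady"],
                                         include_baseline=False)
        for key, cls in study["screen"].classified.items():
            row_id = f"{key[0]}__ko_{key[1]}"
            assert train.labels[row_id] == cls

    def test_baseline_rows_cover_all_states(self, study):
        assert set(study["train"].labels.unique()) == set(study["steady"])


class TestPredictStates:
    def test_attractor_samples_predicted_exactly(self, trained_boosted, attractor_test_samples):
        features, labels = attractor_test_samples
        report = sf.predict_states(trained_boosted, features, truth=labels)
        assert all(v == 1.0 for v in report.per_class_balanced_accuracy.values())

    def test_missing_truth_gives_predictions_only(self, trained_boosted, attractor_test_samples):
        report = sf.predict_states(trained_boosted, attractor_test_samples[0])
        assert report.per_class_balanced_accuracy == {}
        assert report.confusion is None
        assert len(report.predictions) == 4

    def test_sample_order_permutation_permutes_predictions(self, trained_boosted, study):
        truth = study["truth"]
        profiles, _ = sf.generate_activity_profiles(truth, 5, 0.1, 0.2, seed=3)
        boolp = (profiles > 0).astype(int)
        r1 = sf.predict_states(trained_boosted, boolp)
        r2 = sf.predict_states(trained_boosted, boolp.iloc[::-1])
        assert r1.predictions == r2.predictions

    def test_heavily_missing_sample_flagged_but_predicted(self, trained_boosted):
        few = trained_boosted.feature_order[:3]  # >25% of nodes missing
        sample = pd.DataFrame({f: [1] for f in few}, index=["s0"])
        report = sf.predict_states(trained_boosted, sample)
        assert report.flagged_samples == ["s0"]
        assert "s0" in report.predictions

    def test_confusion_rows_sum_to_class_support(self, trained_boosted, study):
        profiles, labels = sf.generate_activity_profiles(study["truth"], 10, 0.1, 0.0, seed=6)
        boolp = (profiles > 0).astype(int)
        report = sf.predict_states(trained_boosted, boolp, truth=labels)
        support = labels.value_counts()
        for cls in report.confusion.index:
            assert report.confusion.loc[cls].sum() == support.get(cls, 0)


class TestBalancedAccuracy:
    def test_perfect_prediction(self):
        assert sf.balanced_accuracy(["A", "B"], ["A", "B"], "A") == 1.0

    def test_always_positive_predictor_is_chance(self):
        assert sf.balanced_accuracy(["A", "B", "B"], ["A", "A", "A"], "A") == 0.5

    def test_confusion_arithmetic_example(self):
        truth = ["A", "A", "B", "B"]
        pred = ["A", "B", "B", "B"]
        assert sf.balanced_accuracy(truth, pred, "A") == pytest.approx(0.75)

    def test_absent_positive_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            sf.balanced_accuracy(["B", "B"], ["A", "B"], "A")

    def test_class_prior_invariance(self, trained_boosted, study):
        """Duplicating one class's test samples leaves its balanced accuracy unchanged."""
        profiles, labels = sf.generate_activity_profiles(study["truth"], 8, 0.2, 0.0, seed=8)
        boolp = (profiles > 0).astype(int)
        preds = pd.Series(sf.predict_states(trained_boosted, boolp).predictions)
        cls = "MES"
        ba = sf.balanced_accuracy(labels, preds.reindex(labels.index), cls)
        dup_idx = list(labels.index) + list(labels.index[labels == cls])
        ba_dup = sf.balanced_accuracy(
            labels.reindex(dup_idx), preds.reindex(dup_idx), cls
        )
        assert ba_dup == pytest.approx(ba)


def stump_attribution_oracle(booster, X, n_classes):
    """Exact Shapley attribution for depth-1 ensembles by stump enumeration.

    For a single-split tree the Shapley value of the split feature is
    leaf(x) minus the cover-weighted mean leaf, and every other feature
    gets zero; the per-class base value accumulates the weighted means
    plus the 0.5 base margin.
    """
    df = booster.trees_to_dataframe()
    n, p = X.shape
    phi = np.zeros((n, n_classes, p))
    base = np.full((n, n_classes), 0.5)
    for tree_id, tree in df.groupby("Tree"):
        cls = tree_id % n_classes
        root = tree[tree["Node"] == 0].iloc[0]
        if root["Feature"] == "Leaf":
            base[:, cls] += root["Gain"]
            continue
        j = int(root["Feature"][1:])
        leaves = {row["ID"]: row for _, row in tree[tree["Feature"] == "Leaf"].iterrows()}
        left, right = leaves[root["Yes"]], leaves[root["No"]]
        mean_leaf = (left["Gain"] * left["Cover"] + right["Gain"] * right["Cover"]) / (
            left["Cover"] + right["Cover"]
        )
        leaf_val = np.where(X[:, j] < root["Split"], left["Gain"], right["Gain"])
        phi[:, cls, j] += leaf_val - mean_leaf
        base[:, cls] += mean_leaf
    return phi, base


class TestAttribution:
    def test_additivity_on_every_sample(self, trained_boosted, study):
        profiles, _ = sf.generate_activity_profiles(study["truth"], 20, 0.2, 0.3, seed=13)
        boolp = (profiles > 0).astype(int)
        attr = sf.attribute_predictions(trained_boosted, boolp)
        assert attr.additivity_error() < 1e-6

    def test_matches_stump_enumeration_oracle(self, trained_boosted, study):
        profiles, _ = sf.generate_activity_profiles(study["truth"], 10, 0.3, 0.0, seed=14)
        X = (profiles > 0).astype(int)
        attr = sf.attribute_predictions(trained_boosted, X)
        phi, base = stump_attribution_oracle(
            trained_boosted.model.get_booster(),
            X[trained_boosted.feature_order].to_numpy(float),
            len(trained_boosted.classes),
        )
        for ci, cls in enumerate(trained_boosted.classes):
            np.testing.assert_allclose(
                attr.contributions[cls].to_numpy(), phi[:, ci, :], atol=1e-5
            )
            np.testing.assert_allclose(attr.base_values[cls], base[:, ci], atol=1e-5)

    def test_unused_feature_gets_zero_attribution(self, separable_toy):
        X = separable_toy.features.copy()
        X["constant"] = 0  # never splittable
        train = sf.TrainingSet(features=X, labels=separable_toy.labels)
        clf = sf.train_classifier(train, "boosted_trees", {"subsample": 1.0}, seed=3)
        attr = sf.attribute_predictions(clf, X)
        for contrib in attr.contributions.values():
            assert (contrib["constant"] == 0).all()

    def test_non_tree_model_refused(self, separable_toy):
        clf = sf.train_classifier(separable_toy, "knn", {"n_neighbors": 3}, seed=1)
        with pytest.raises(ValueError, match="boosted_trees"):
            sf.attribute_predictions(clf, separable_toy.features)


class TestComparePairedSamples:
    def _attr(self, clf, frame):
        return sf.attribute_predictions(clf, frame)

    def test_identical_profiles_report_no_change(self, trained_boosted, attractor_test_samples):
        features, _ = attractor_test_samples
        attr = self._attr(trained_boosted, features)
        preds = sf.predict_states(trained_boosted, features).predictions
        out = sf.compare_paired_samples(attr, attr, preds, preds)
        for t in out.values():
            assert t.changed_features == []
            assert t.ranked_supporting == []
            assert t.state_before == t.state_after

    def test_flipping_discriminative_features_tops_ranking(self, trained_boosted, study):
        steady = study["steady"]
        nodes = study["truth"].network.nodes
        primary = pd.DataFrame(
            {n: {"patient": steady["NPC"][n]} for n in nodes}
        )
        recurrent = pd.DataFrame(
            {n: {"patient": steady["MES"][n]} for n in nodes}
        )
        attr_p = self._attr(trained_boosted, primary)
        attr_r = self._attr(trained_boosted, recurrent)
        pred_p = sf.predict_states(trained_boosted, primary).predictions
        pred_r = sf.predict_states(trained_boosted, recurrent).predictions
        out = sf.compare_paired_samples(attr_p, attr_r, pred_p, pred_r)
        t = out["patient"]
        assert t.state_before == "NPC" and t.state_after == "MES"
        changed = {n for n in nodes if steady["NPC"][n] != steady["MES"][n]}
        assert set(t.changed_features) == changed
        # ranked features are exactly the changed ones that pushed toward MES
        assert set(f for f, _ in t.ranked_supporting) <= changed
        assert len(t.ranked_supporting) > 0
        deltas = [d for _, d in t.ranked_supporting]
        assert deltas == sorted(deltas, reverse=True)

    def test_unpaired_ids_skipped_with_warning(self, trained_boosted, attractor_test_samples):
        features, _ = attractor_test_samples
        attr_all = self._attr(trained_boosted, features)
        attr_sub = self._attr(trained_boosted, features.iloc[:2])
        preds = sf.predict_states(trained_boosted, features).predictions
        with pytest.warns(UserWarning, match="unpaired"):
            out = sf.compare_paired_samples(attr_all, attr_sub, preds, preds)
        assert len(out) == 2
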