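"""Cell-state prediction from Boolean profiles, with additive attributions.

Classifiers are trained on knockout-simulation steady states (features:
the binary node vector; label: the cell state the outcome was classified
into) and evaluated on booleanized activity profiles by one-vs-rest
balanced accuracy, the metric of choice under heavy class imbalance.
For boosted trees, per-sample per-class additive (TreeSHAP) feature
attributions are computed and used to explain paired primary/recurrent
sample transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .boolnet import STATE_ORDER
from .koscreen import KOScreenResult

__all__ = [
    "TrainingSet",
    "StateClassifier",
    "PredictionReport",
    "AttributionResult",
    "PairTransition",
    "training_set_from_screen",
    "train_classifier",
    "predict_states",
    "balanced_accuracy",
    "attribute_predictions",
    "compare_paired_samples",
    "permutation_feature_filter",
]

MODEL_KINDS = ("multinomial_elasticnet", "knn", "random_forest", "boosted_trees")

#: Hyperparameter defaults mirror the study settings: depth-1 boosted
#: trees (100 rounds, lr 0.1, subsample 0.1), 1000-tree random forest with
#: 35 features per split, 13-neighbor KNN, and elastic net with mixing
#: parameter 0.14 (penalty strength by internal cross-validation).
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "boosted_trees": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 1, "subsample": 0.1},
    "random_forest": {"n_estimators": 1000, "max_features": 35},
    "knn": {"n_neighbors": 13},
    "multinomial_elasticnet": {"l1_ratio": 0.14, "cv": 10},
}


#: Training-set size the stock hyperparameters were tuned for (a knockout
#: screen of ~146 simulations).
REFERENCE_TRAINING_SIZE = 146


def scaled_hyperparams(model_kind: str, n_train: int) -> dict:
    """Adapt size-coupled defaults to a smaller training set.

    ``subsample`` = 0.1 means ~15 rows per boosting tree at the reference
    training size; on a smaller screen the same fraction starves each
    stump, so the absolute rows-per-tree is preserved instead.  The KNN
    neighbor count is likewise kept proportional (floor 3).  Other
    hyperparameters are returned unchanged.
    """
    hp = dict(DEFAULT_HYPERPARAMS[model_kind])
    if model_kind == "boosted_trees":
        rows_per_tree = hp["subsample"] * REFERENCE_TRAINING_SIZE
        hp["subsample"] = float(min(1.0, max(hp["subsample"], rows_per_tree / n_train)))
    elif model_kind == "knn":
        frac = hp["n_neighbors"] / REFERENCE_TRAINING_SIZE
        hp["n_neighbors"] = max(3, round(frac * n_train))
    return hp


@dataclass
class TrainingSet:
    """Binary simulation × node feature matrix with cell-state labels."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if not self.features.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.features.index)
        if self.labels.isna().any():
            raise ValueError("every simulation needs a label")
        vals = self.features.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix must be binary")


def training_set_from_screen(
    screen: KOScreenResult,
    steady_states: Mapping[str, "BooleanState"] | None = None,
    include_baseline: bool = True,
) -> TrainingSet:
    """Assemble the ML training set from a knockout screen.

    Each knockout outcome contributes its steady-state node vector,
    labeled with the state the outcome was classified into (the resulting
    phenotype, not the start state).  With ``include_baseline`` the four
    unperturbed steady states are appended as one row each, which
    guarantees all four classes appear even when no knockout escapes its
    basin.
    """
    rows, labels, ids = [], [], []
    nodes = None
    for key, state in screen.outcome_states.items():
        if nodes is None:
            nodes = list(state)
        rows.append([state[n] for n in nodes])
        labels.append(screen.classified[key])
        ids.append(f"{key[0]}__ko_{key[1]}")
    if include_baseline and steady_states is not None:
        for name, state in steady_states.items():
            rows.append([state[n] for n in nodes])
            labels.append(name)
            ids.append(f"{name}__baseline")
    features = pd.DataFrame(rows, index=ids, columns=nodes)
    return TrainingSet(features=features, labels=pd.Series(labels, index=ids, name="state"))


@dataclass
class StateClassifier:
    """Fitted model handle with frozen feature and class order."""

    kind: str
    model: object
    feature_order: list[str]
    classes: list[str]
    majority_fill: pd.Series
    seed: int

    def predict_labels(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.model.predict(X[self.feature_order].to_numpy())
        if raw.dtype.kind in "iuf":
            return np.array([self.classes[int(i)] for i in raw])
        return raw


def train_classifier(
    train: TrainingSet,
    model_kind: str,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> StateClassifier:
    """Fit one of the four model families on the simulation training set."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    classes = sorted(train.labels.unique())
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    hp = dict(DEFAULT_HYPERPARAMS[model_kind])
    hp.update(hyperparams or {})
    X = train.features.to_numpy(dtype=float)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in train.labels])
    n_samples, n_features = X.shape

    if model_kind == "boosted_trees":
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            max_depth=hp["max_depth"],
            subsample=hp["subsample"],
            objective="multi:softprob" if len(classes) > 2 else "binary:logistic",
            base_score=0.5,
            random_state=seed,
            n_jobs=1,
            tree_method="exact",
        )
        model.fit(X, y)
    elif model_kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        max_features = hp["max_features"]
        if isinstance(max_features, int) and max_features > n_features:
            warnings.warn(
                f"max_features={max_features} > {n_features} features; clipping"
            )
            max_features = n_features
        model = RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
        model.fit(X, y)
    elif model_kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        k = min(hp["n_neighbors"], n_samples)
        model = KNeighborsClassifier(n_neighbors=k)
        model.fit(X, y)
    else:  # multinomial_elasticnet
        from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

        min_class = int(np.bincount(y).min())
        cv = min(hp["cv"], min_class)
        if cv >= 2:
            # elastic net implied by l1_ratios; strength picked over Cs by CV
            model = LogisticRegressionCV(
                solver="saga",
                l1_ratios=[hp["l1_ratio"]],
                Cs=5,
                cv=cv,
                scoring="accuracy",
                max_iter=5000,
                random_state=seed,
            )
        else:
            model = LogisticRegression(
                solver="saga",
                l1_ratio=hp["l1_ratio"],
                C=1.0,
                max_iter=5000,
                random_state=seed,
            )
        model.fit(X, y)

    majority = (train.features.mean(axis=0) >= 0.5).astype(int)
    return StateClassifier(
        kind=model_kind,
        model=model,
        feature_order=list(train.features.columns),
        classes=classes,
        majority_fill=majority,
        seed=seed,
    )


@dataclass
class PredictionReport:
    predictions: dict[str, str]
    per_class_balanced_accuracy: dict[str, float] = field(default_factory=dict)
    confusion: pd.DataFrame | None = None
    flagged_samples: list[str] = field(default_factory=list)


def _align_features(clf: StateClassifier, samples: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    aligned = samples.reindex(columns=clf.feature_order)
    flagged = []
    missing_cols = aligned.columns[aligned.isna().all(axis=0)]
    frac_missing = aligned.isna().mean(axis=1)
    for sid in aligned.index[frac_missing > 0.25]:
        flagged.append(str(sid))
    for col in aligned.columns:
        if aligned[col].isna().any():
            aligned[col] = aligned[col].fillna(clf.majority_fill[col])
    return aligned.astype(float), flagged


def predict_states(
    clf: StateClassifier,
    samples: pd.DataFrame,
    truth: Mapping[str, str] | pd.Series | None = None,
) -> PredictionReport:
    """Predict the dominant cell state of each Boolean profile.

    Features are reindexed to the training order; nodes absent from a
    sample's table are filled with the training-set majority value, and
    samples missing more than 25% of features are flagged (but still
    predicted).  When truth labels are supplied, one-vs-rest balanced
    accuracy per class and a confusion matrix are reported.
    """
    X, flagged = _align_features(clf, samples)
    labels = clf.predict_labels(X)
    predictions = dict(zip((str(i) for i in samples.index), labels))
    report = PredictionReport(predictions=predictions, flagged_samples=flagged)
    if truth is not None and len(truth) > 0:
        truth_s = pd.Series(truth).reindex(samples.index)
        pred_s = pd.Series(labels, index=samples.index)
        per_class = {}
        for cls in clf.classes:
            if (truth_s == cls).any():
                per_class[cls] = balanced_accuracy(truth_s, pred_s, cls)
        report.per_class_balanced_accuracy = per_class
        conf = pd.crosstab(truth_s, pred_s).reindex(
            index=clf.classes, columns=clf.classes, fill_value=0
        )
        report.confusion = conf
    return report


def balanced_accuracy(truth, predicted, positive_class: str) -> float:
    """One-vs-rest balanced accuracy: (sensitivity + specificity) / 2."""
    t = np.asarray(pd.Series(truth))
    p = np.asarray(pd.Series(predicted))
    if len(t) != len(p) or len(t) == 0:
        raise ValueError("truth and predicted must be equal-length and non-empty")
    pos = t == positive_class
    if not pos.any():
        raise ValueError(f"positive class {positive_class!r} absent from truth")
    sens = float(np.mean(p[pos] == positive_class))
    neg = ~pos
    spec = float(np.mean(p[neg] != positive_class)) if neg.any() else 1.0
    return (sens + spec) / 2.0


@dataclass
class AttributionResult:
    """Additive per-sample per-class feature attributions.

    For every sample and class, ``base_values[class] + contributions
    [class].loc[sample].sum()`` equals the model's margin output.  The
    sample feature values used are kept for paired comparisons.
    """

    contributions: dict[str, pd.DataFrame]  # class -> samples × features
    base_values: dict[str, pd.Series]  # class -> per-sample base value
    margins: pd.DataFrame  # samples × classes
    features: pd.DataFrame  # aligned sample features

    def additivity_error(self) -> float:
        err = 0.0
        for cls, contrib in self.contributions.items():
            recon = contrib.sum(axis=1) + self.base_values[cls]
            err = max(err, float((recon - self.margins[cls]).abs().max()))
        return err


def attribute_predictions(clf: StateClassifier, samples: pd.DataFrame) -> AttributionResult:
    """TreeSHAP additive attributions for a boosted-trees classifier.

    Contributions are on the margin (log-odds) scale per class; for
    depth-1 trees each stump contributes only through its split feature.
    Non-tree models are refused (use permutation importance instead).
    """
    if clf.kind != "boosted_trees":
        raise ValueError(
            "attributions require a boosted_trees model; "
            "use permutation importance for other model kinds"
        )
    import xgboost as xgb

    X, _ = _align_features(clf, samples)
    booster = clf.model.get_booster()
    dmat = xgb.DMatrix(X.to_numpy())
    contribs = booster.predict(dmat, pred_contribs=True).astype(np.float64)
    margins = booster.predict(dmat, output_margin=True).astype(np.float64)
    index = samples.index
    if contribs.ndim == 2:  # binary model: single margin column
        contribs = contribs[:, None, :]
        margins = margins[:, None]
        class_names = [clf.classes[1]]
    else:
        class_names = clf.classes
    contributions, base_values = {}, {}
    for ci, cls in enumerate(class_names):
        contributions[cls] = pd.DataFrame(
            contribs[:, ci, :-1], index=index, columns=clf.feature_order
        )
        base_values[cls] = pd.Series(contribs[:, ci, -1], index=index)
    margin_df = pd.DataFrame(margins, index=index, columns=class_names)
    return AttributionResult(
        contributions=contributions,
        base_values=base_values,
        margins=margin_df,
        features=X,
    )


@dataclass
class PairTransition:
    """Primary → recurrent change summary for one patient."""

    sample_id: str
    state_before: str
    state_after: str
    ranked_supporting: list[tuple[str, float]]  # (feature, Δattribution toward after-state)
    changed_negligible: list[str]
    changed_features: list[str]


def compare_paired_samples(
    attr_primary: AttributionResult,
    attr_recurrent: AttributionResult,
    pred_primary: Mapping[str, str],
    pred_recurrent: Mapping[str, str],
    negligible_tol: float = 1e-9,
) -> dict[str, PairTransition]:
    """Explain paired primary/recurrent predictions through attribution shifts.

    For each paired sample id the features that changed input value are
    split into those whose attribution toward the recurrent predicted
    state moved in the supporting (positive) direction — ranked by the
    size of that shift — and those whose attribution barely moved.
    Sample ids present in only one cohort are skipped with a warning.
    """
    if list(attr_primary.features.columns) != list(attr_recurrent.features.columns):
        raise ValueError("paired attributions must share the feature space")
    ids_p = set(map(str, attr_primary.features.index))
    ids_r = set(map(str, attr_recurrent.features.index))
    unpaired = sorted(ids_p ^ ids_r)
    if unpaired:
        warnings.warn(f"skipping {len(unpaired)} unpaired sample id(s): {unpaired[:5]}")
    out: dict[str, PairTransition] = {}
    for sid in sorted(ids_p & ids_r):
        before = pred_primary[sid]
        after = pred_recurrent[sid]
        fp = attr_primary.features.loc[sid]
        fr = attr_recurrent.features.loc[sid]
        changed = [c for c in attr_primary.features.columns if fp[c] != fr[c]]
        phi_p = attr_primary.contributions[after].loc[sid]
        phi_r = attr_recurrent.contributions[after].loc[sid]
        delta = phi_r - phi_p
        supporting = sorted(
            ((c, float(delta[c])) for c in changed if delta[c] > negligible_tol),
            key=lambda kv: -kv[1],
        )
        negligible = [c for c in changed if abs(delta[c]) <= negligible_tol]
        out[sid] = PairTransition(
            sample_id=sid,
            state_before=before,
            state_after=after,
            ranked_supporting=supporting,
            changed_negligible=negligible,
            changed_features=changed,
        )
    return out


def permutation_feature_filter(
    train: TrainingSet,
    model_kind: str = "boosted_trees",
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[str]:
    """Optional importance-threshold feature selector (off by default).

    Fits the model, then permutes each feature column ``n_shuffles``
    times and keeps features whose mean drop in training accuracy is
    positive.  Depth-1 boosted trees self-select features, so this is an
    opt-in filter, not a pipeline stage.
    """
    clf = train_classifier(train, model_kind, seed=seed)
    X = train.features.copy()
    y = train.labels.to_numpy()
    baseline = float(np.mean(clf.predict_labels(X) == y))
    rng = np.random.default_rng(seed)
    keep = []
    for col in X.columns:
        drops = []
        for _ in range(n_shuffles):
            shuffled = X.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            acc = float(np.mean(clf.predict_labels(shuffled) == y))
            drops.append(baseline - acc)
        if float(np.mean(drops)) > 0:
            keep.append(col)
    return keep
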