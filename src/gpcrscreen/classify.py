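"""Random-forest agonist/antagonist classification.

Two parallel classifiers are supported by the same machinery: one on
per-pose interaction-fingerprint rows (optionally with the docking score
as an extra feature) and one on per-molecule circular-fingerprint bits.
Samples are pose-level but labels are molecule-level, so cross-validation
uses grouped stratified folds: all poses of a molecule stay on one side
of every split, which is what prevents pose-identity leakage from
inflating the metrics.

Forests run with library-default hyperparameters (no tuning) and a
mandatory seed; molecule-level antagonist probability is the arithmetic
mean of per-pose probabilities, and the probability filter keeps
candidates at or above the cutoff (default 0.84).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from .treeshap import AttributionReport, shap_values

logger = logging.getLogger(__name__)

LABEL_AGONIST = 1
LABEL_ANTAGONIST = 0
DEFAULT_TREES = 500
DEFAULT_PROBABILITY_THRESHOLD = 0.84


@dataclass
class LabeledSample:
    features: np.ndarray
    label: int                 # agonist=1, antagonist=0
    group_id: str              # molecule id; keeps poses together in CV
    pose_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.label not in (LABEL_AGONIST, LABEL_ANTAGONIST):
            raise ValueError("label must be agonist=1 or antagonist=0")
        if not self.group_id:
            raise ValueError("group_id must be non-empty")


@dataclass
class SampleSet:
    """Column-wise view of a list of labeled samples."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @classmethod
    def from_samples(cls, samples: Sequence[LabeledSample],
                     feature_names: Sequence[str] | None = None) -> "SampleSet":
        if not samples:
            raise ValueError("no samples")
        lengths = {s.features.shape[0] for s in samples}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent feature lengths {sorted(lengths)}")
        X = np.stack([s.features for s in samples])
        y = np.array([s.label for s in samples])
        groups = np.array([s.group_id for s in samples])
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(X.shape[1])])
        return cls(X=X, y=y, groups=groups, feature_names=names)


def grouped_stratified_folds(y: np.ndarray, groups: np.ndarray, k: int = 5,
                             seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, never splitting a group.

    Stratification keeps per-fold label proportions as close to the
    global proportion as the group sizes allow.  Returns an integer fold
    index per sample.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < k:
        raise ValueError(f"need >= {k} distinct groups, "
                         f"got {len(np.unique(groups))}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(y), -1, dtype=int)
    for fold, (_, test_idx) in enumerate(cv.split(np.zeros_like(y), y, groups)):
        folds[test_idx] = fold
    assert (folds >= 0).all()
    return folds


def assert_no_group_leakage(folds: np.ndarray, groups: np.ndarray) -> None:
    """Every group must live entirely inside a single fold."""
    groups = np.asarray(groups)
    for g in np.unique(groups):
        gf = np.unique(folds[groups == g])
        if len(gf) != 1:
            raise AssertionError(f"group {g!r} split across folds {gf}")


def train_rf(X: np.ndarray, y: np.ndarray, trees: int = DEFAULT_TREES,
             seed: int = 0) -> RandomForestClassifier:
    """Fit a random forest with library-default hyperparameters.

    No hyperparameter search is performed, to avoid overfitting the small
    labeled libraries this is meant for.  Deterministic for a fixed seed.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    model = RandomForestClassifier(n_estimators=trees, random_state=seed,
                                   n_jobs=1)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def _antagonist_column(model: RandomForestClassifier) -> int:
    return int(np.where(model.classes_ == LABEL_ANTAGONIST)[0][0])


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             scores: Optional[np.ndarray] = None) -> dict[str, float]:
    """Binary classification metrics from the confusion matrix.

    Positive class is agonist=1.  precision = TP/(TP+FP), recall =
    TP/(TP+FN), F1 = harmonic mean, accuracy = (TP+TN)/n; ROC AUC (from
    ``scores``, the positive-class score) is the trapezoidal area under
    the ROC curve.  Zero-denominator metrics come back as 0 with a
    warning so CV tables stay numeric.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))

    def safe_div(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: zero denominator, reporting 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    precision = safe_div(tp, tp + fp, "precision")
    recall = safe_div(tp, tp + fn, "recall")
    f1 = safe_div(2 * precision * recall, precision + recall, "f1")
    accuracy = (tp + tn) / len(y_true)
    out = {"precision": precision, "recall": recall, "f1": f1,
           "accuracy": accuracy}
    if scores is not None:
        if len(np.unique(y_true)) < 2:
            raise ValueError("ROC AUC undefined for single-class labels")
        out["roc_auc"] = float(roc_auc_score(y_true, scores))
    return out


@dataclass
class CVReport:
    per_fold: pd.DataFrame      # one row per fold
    folds: np.ndarray           # fold index per sample

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean(axis=0)


def cross_validate(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   k: int = 5, trees: int = DEFAULT_TREES, seed: int = 0
                   ) -> CVReport:
    """Grouped stratified k-fold cross-validation of the forest.

    Leakage is re-checked on every run: no molecule's poses ever appear
    in both the training and test side of a fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    folds = grouped_stratified_folds(y, groups, k=k, seed=seed)
    assert_no_group_leakage(folds, groups)
    rows = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        assert not set(groups[train]) & set(groups[test])
        model = train_rf(X[train], y[train], trees=trees, seed=seed)
        pos = int(np.where(model.classes_ == 1)[0][0])
        prob_pos = model.predict_proba(X[test])[:, pos]
        metrics = evaluate(y[test], model.predict(X[test]), scores=prob_pos)
        metrics["fold"] = fold
        rows.append(metrics)
    per_fold = pd.DataFrame(rows).set_index("fold")
    return CVReport(per_fold=per_fold, folds=folds)


def predict_molecule_probability(model: RandomForestClassifier,
                                 pose_features: np.ndarray) -> float:
    """Molecule-level antagonist probability: mean over its poses."""
    pose_features = np.asarray(pose_features, dtype=float)
    if pose_features.ndim == 1:
        pose_features = pose_features[None, :]
    if pose_features.shape[0] == 0:
        raise ValueError("molecule has no poses")
    if pose_features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature length {pose_features.shape[1]} != model's "
            f"{model.n_features_in_}")
    probs = model.predict_proba(pose_features)[:, _antagonist_column(model)]
    return float(probs.mean())


def filter_by_probability(probabilities: Sequence[float],
                          threshold: float = DEFAULT_PROBABILITY_THRESHOLD
                          ) -> list[int]:
    """Indices of candidates retained by the probability filter.

    Boundary inclusive: a candidate exactly at the threshold survives
    (only strictly lower probabilities are discarded).  Input order is
    preserved.
    """
    probs = np.asarray(probabilities, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return [i for i, p in enumerate(probs) if p >= threshold]


def shap_attributions(model: RandomForestClassifier, X: np.ndarray,
                      feature_names: Sequence[str] | None = None
                      ) -> AttributionReport:
    """Shapley attributions of the antagonist probability per sample.

    Additivity (base value + attributions = predicted probability) is an
    invariant of the underlying tree recursion and is asserted here.
    """
    report = shap_values(model, X, feature_names=feature_names,
                         class_index=_antagonist_column(model))
    recon = report.base_value + report.values.sum(axis=1)
    err = np.abs(recon - report.predictions).max() if len(recon) else 0.0
    if err > 1e-6:
        raise AssertionError(f"local accuracy violated: max error {err:g}")
    return report


def attribution_summary(report: AttributionReport) -> pd.DataFrame:
    """Global view: mean |attribution| and sign consistency per feature."""
    vals = report.values
    with np.errstate(invalid="ignore"):
        sign_frac = np.where(
            np.abs(vals).sum(axis=0) > 0,
            np.maximum((vals > 0).mean(axis=0), (vals < 0).mean(axis=0)),
            1.0)
    df = pd.DataFrame({
        "feature": report.feature_names,
        "mean_abs_attribution": np.abs(vals).mean(axis=0),
        "sign_consistency": sign_frac,
    })
    return df.sort_values("mean_abs_attribution", ascending=False,
                          ignore_index=True)
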