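"""Per-target Random Forest activity classifiers and the validation metric panel.

The classifier emits an active-class probability (the fraction of trees voting
active); validation reports accuracy, sensitivity, specificity, PPV, NPV, the
Matthews correlation coefficient and ROC-AUC, on a held-out stratified test
set and under stratified k-fold cross-validation. The model's average
specificity across the two validation modes (ESP) later weights the
ligand-based probability in the consensus score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .chem_io import DescriptorMatrix, LabeledDataset

__all__ = [
    "SplitSpec",
    "ForestSpec",
    "ConfusionMatrix",
    "PerformanceReport",
    "TrainedModel",
    "stratified_split",
    "train_forest",
    "predict_activity_probability",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
    "model_esp",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: 80/20 stratified by class, seeded."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ForestSpec:
    """Random Forest hyperparameters: 250 trees, seed 1 by default."""

    n_trees: int = 250
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary-classification counts: VP/VN true, FP/FN false calls."""

    vp: int
    vn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.vp, self.vn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one record")

    @property
    def total(self) -> int:
        return self.vp + self.vn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            vp=int(np.sum((y_true == 1) & (y_pred == 1))),
            vn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class PerformanceReport:
    """Validation metric panel; a metric with a zero denominator is None."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    mcc: float | None
    roc_auc: float | None = None
    validation_mode: str = "test"  # "test" or "cross"

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
        }


@dataclass
class TrainedModel:
    """Fitted forest plus the descriptor names it expects and its provenance."""

    target_id: str
    forest: RandomForestClassifier
    descriptor_names: list[str]
    spec: ForestSpec
    esp: float | None = None  # mean of test and cross-validated specificity

    def __post_init__(self) -> None:
        if self.esp is not None and not 0 <= self.esp <= 1:
            raise ValueError("esp must lie in [0, 1]")


def stratified_split(
    dataset: LabeledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition a labelled dataset into disjoint, exhaustive train/test sets.

    Per-class train counts land within one compound of
    ``spec.train_fraction`` of each class; the partition is deterministic for
    a fixed seed. Each class needs at least two members.
    """
    y = dataset.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 members for a stratified split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)

    def subset(sel: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            target=dataset.target,
            X=DescriptorMatrix(
                compound_ids=[dataset.X.compound_ids[i] for i in sel],
                descriptor_names=dataset.X.descriptor_names,
                values=dataset.X.values[sel],
            ),
            y=y[sel],
        )

    return subset(train_idx), subset(test_idx)


def train_forest(
    train: LabeledDataset, spec: ForestSpec = ForestSpec()
) -> TrainedModel:
    """Fit the Random Forest classifier (250 trees, seeded) on a training set."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
    )
    forest.fit(train.X.values, train.y)
    return TrainedModel(
        target_id=train.target.target_id,
        forest=forest,
        descriptor_names=list(train.X.descriptor_names),
        spec=spec,
    )


def predict_activity_probability(
    model: TrainedModel, X: DescriptorMatrix
) -> np.ndarray:
    """Per-compound active-class probability: the fraction of trees voting active."""
    if list(X.descriptor_names) != model.descriptor_names:
        raise ValueError(
            "descriptor names do not match the model's training descriptors"
        )
    proba = model.forest.predict_proba(X.values)
    active_col = list(model.forest.classes_).index(1)
    return proba[:, active_col]


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(
    cm: ConfusionMatrix, validation_mode: str = "test"
) -> PerformanceReport:
    """Compute the metric panel from confusion counts.

    MCC = (VP*VN - FP*FN) / sqrt((VP+FP)(VP+FN)(VN+FP)(VN+FN)), the Pearson
    correlation of the binary prediction and truth vectors: +1 is a perfect
    prediction, 0 a random one, -1 total disagreement. A metric whose
    denominator is zero is reported as None (undefined), never as 0.
    """
    vp, vn, fp, fn = cm.vp, cm.vn, cm.fp, cm.fn
    denom = (vp + fp) * (vp + fn) * (vn + fp) * (vn + fn)
    mcc = (vp * vn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return PerformanceReport(
        accuracy=_safe_div(vp + vn, cm.total),
        sensitivity=_safe_div(vp, vp + fn),
        specificity=_safe_div(vn, vn + fp),
        ppv=_safe_div(vp, vp + fp),
        npv=_safe_div(vn, vn + fn),
        mcc=mcc,
        validation_mode=validation_mode,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve.

    Equals the probability that a randomly drawn active outranks a randomly
    drawn inactive, with ties counted half.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _score_predictions(
    y_true: np.ndarray, probs: np.ndarray, validation_mode: str
) -> PerformanceReport:
    # probability exactly 0.5 is classified active, consistent with the
    # screening rule "equal to or greater than 0.5"
    y_pred = (probs >= 0.5).astype(int)
    report = confusion_metrics(
        ConfusionMatrix.from_predictions(y_true, y_pred), validation_mode
    )
    report.roc_auc = roc_auc(probs, y_true)
    return report


def validate_on_test(model: TrainedModel, test: LabeledDataset) -> PerformanceReport:
    """External validation: score the held-out test set."""
    probs = predict_activity_probability(model, test.X)
    return _score_predictions(test.y, probs, "test")


def cross_validate(
    dataset: LabeledDataset, spec: ForestSpec = ForestSpec(), k: int = 10
) -> PerformanceReport:
    """Stratified k-fold cross-validation (default k=10).

    Out-of-fold probabilities are pooled over all folds and scored once,
    so every compound contributes exactly one prediction. Deterministic for
    fixed seeds; fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    counts = np.bincount(dataset.y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    probs = np.empty(len(dataset.y), dtype=float)
    for train_idx, test_idx in skf.split(dataset.X.values, dataset.y):
        forest = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
        )
        forest.fit(dataset.X.values[train_idx], dataset.y[train_idx])
        proba = forest.predict_proba(dataset.X.values[test_idx])
        active_col = list(forest.classes_).index(1)
        probs[test_idx] = proba[:, active_col]
    return _score_predictions(dataset.y, probs, "cross")


def model_esp(
    test_report: PerformanceReport, cross_report: PerformanceReport
) -> float:
    """ESP: the model's average specificity over test and cross-validation.

    This is the weight the consensus score places on the ligand-based
    probability.
    """
    for rep, mode in ((test_report, "test"), (cross_report, "cross")):
        if rep.specificity is None:
            raise ValueError(f"{mode} report has undefined specificity")
    return (test_report.specificity + cross_report.specificity) / 2.0
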