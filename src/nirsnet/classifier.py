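"""RBF-SVM training, leave-one-out cross-validation and performance metrics.

The classifier is a support vector machine with a radial basis function
kernel at canonical libsvm defaults (C = 1, gamma = 1/n_features).  Features
are z-scored with training-fold statistics by default, since RBF kernels on
raw degree counts (0..C-1) are scale-sensitive; ``standardize=False`` gives
the literal unscaled variant.

Leave-one-out cross-validation holds out each subject once (n rounds for n
subjects).  Feature selection can run once on the whole sample before LOOCV
("paper" mode) or be re-run inside every training fold ("fold" mode, the
statistically sound default: the held-out subject never influences which
(metric, sparsity) is chosen).

Performance is summarised by the confusion matrix with patients (+1) as the
positive class and

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SS  = TP / (TP + FN)          (sensitivity, patient recall)
    TNR = TN / (TN + FP)          (specificity, control recall)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.svm import SVC

from .dataio import GROUP_CONTROL, GROUP_PATIENT
from .features import (
    FeatureMatrix,
    FeatureTensor,
    group_difference_scan,
    select_feature_vector,
)

__all__ = [
    "SVMParams",
    "SVMModel",
    "ConfusionMatrix",
    "FoldRecord",
    "PerformanceReport",
    "train_svm",
    "predict",
    "loocv",
    "performance_metrics",
]


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters; defaults mirror libsvm's."""

    kernel: Literal["rbf"] = "rbf"
    C: float = 1.0
    gamma: float | Literal["auto"] = "auto"  # auto = 1 / n_features
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma != "auto" and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class SVMModel:
    """Fitted SVM plus the training-fold standardisation statistics."""

    svc: SVC
    mean: np.ndarray
    scale: np.ndarray
    params: SVMParams
    n_features: int


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class FoldRecord:
    subject_id: str
    true_label: int
    predicted_label: int
    chosen_metric: str | None = None
    chosen_sparsity: float | None = None


@dataclass
class PerformanceReport:
    """ACC/SS/TNR (fractions in [0,1]) plus confusion counts and folds."""

    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    folds: list[FoldRecord] = field(default_factory=list)
    feature_description: str = ""

    @property
    def accuracy_pct(self) -> float:
        return round(self.accuracy * 100, 1)

    @property
    def sensitivity_pct(self) -> float:
        return round(self.sensitivity * 100, 1)

    @property
    def specificity_pct(self) -> float:
        return round(self.specificity * 100, 1)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "TP": self.confusion.tp,
                "FN": self.confusion.fn,
                "FP": self.confusion.fp,
                "TN": self.confusion.tn,
            },
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "feature_description": self.feature_description,
            "folds": [
                {
                    "subject_id": f.subject_id,
                    "true": f.true_label,
                    "predicted": f.predicted_label,
                    "chosen_metric": f.chosen_metric,
                    "chosen_sparsity": f.chosen_sparsity,
                }
                for f in self.folds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceReport":
        cm = ConfusionMatrix(
            tp=d["confusion"]["TP"],
            fn=d["confusion"]["FN"],
            fp=d["confusion"]["FP"],
            tn=d["confusion"]["TN"],
        )
        return cls(
            confusion=cm,
            accuracy=d["accuracy"],
            sensitivity=d["sensitivity"],
            specificity=d["specificity"],
            feature_description=d.get("feature_description", ""),
            folds=[
                FoldRecord(
                    subject_id=f["subject_id"],
                    true_label=f["true"],
                    predicted_label=f["predicted"],
                    chosen_metric=f.get("chosen_metric"),
                    chosen_sparsity=f.get("chosen_sparsity"),
                )
                for f in d.get("folds", [])
            ],
        )


def _resolve_gamma(params: SVMParams, n_features: int) -> float:
    if params.gamma == "auto":
        return 1.0 / n_features
    return float(params.gamma)


def train_svm(X: np.ndarray, y: np.ndarray, params: SVMParams = SVMParams()) -> SVMModel:
    """Fit an RBF-SVM; deterministic given fixed inputs.

    Standardisation statistics (mean, scale) are computed from the training
    rows only; zero-variance features get scale 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training set contains a single class {classes.tolist()}")
    if params.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    svc = SVC(kernel="rbf", C=params.C, gamma=_resolve_gamma(params, X.shape[1]))
    svc.fit(Xs, y)
    return SVMModel(svc=svc, mean=mean, scale=scale, params=params, n_features=X.shape[1])


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Predict +1/-1 labels; a zero decision value maps to +1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.n_features}"
        )
    dec = model.svc.decision_function((X - model.mean) / model.scale)
    # decision_function > 0 corresponds to classes_[1] == +1
    return np.where(dec >= 0, GROUP_PATIENT, GROUP_CONTROL)


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return model.svc.decision_function((X - model.mean) / model.scale)


def _confusion_from_folds(folds: list[FoldRecord]) -> ConfusionMatrix:
    tp = sum(1 for f in folds if f.true_label == GROUP_PATIENT and f.predicted_label == GROUP_PATIENT)
    fn = sum(1 for f in folds if f.true_label == GROUP_PATIENT and f.predicted_label == GROUP_CONTROL)
    tn = sum(1 for f in folds if f.true_label == GROUP_CONTROL and f.predicted_label == GROUP_CONTROL)
    fp = sum(1 for f in folds if f.true_label == GROUP_CONTROL and f.predicted_label == GROUP_PATIENT)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def loocv(
    features: FeatureMatrix | None = None,
    *,
    tensor: FeatureTensor | None = None,
    params: SVMParams = SVMParams(),
    selection_mode: Literal["paper", "fold"] = "paper",
    alpha: float = 0.05,
) -> PerformanceReport:
    """Leave-one-out cross-validation over all subjects.

    ``paper`` mode classifies a pre-selected FeatureMatrix (selection done
    once, outside the folds).  ``fold`` mode takes the full FeatureTensor
    and re-runs the group-difference scan on each training fold before
    slicing that fold's feature matrix — the held-out subject never touches
    selection.
    """
    if selection_mode == "paper":
        if features is None:
            raise ValueError("paper mode requires a pre-selected FeatureMatrix")
        labels = features.labels
        subject_ids = features.subject_ids or [f"s{i + 1:03d}" for i in range(labels.size)]
    elif selection_mode == "fold":
        if tensor is None:
            raise ValueError("fold mode requires the full FeatureTensor")
        labels = tensor.labels
        subject_ids = tensor.subject_ids
    else:
        raise ValueError(f"unknown selection mode {selection_mode!r}")

    n = labels.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if np.unique(labels).size < 2:
        raise ValueError("cohort must contain both classes")

    folds: list[FoldRecord] = []
    for i in range(n):
        train_rows = np.r_[0:i, i + 1 : n]
        if np.unique(labels[train_rows]).size < 2:
            raise ValueError(
                f"training fold after removing subject {subject_ids[i]!r} "
                "contains a single class"
            )
        if selection_mode == "fold":
            sub = tensor.subset(train_rows)
            sel = group_difference_scan(sub, alpha=alpha)
            fm = select_feature_vector(tensor, sel.chosen_metric, sel.chosen_sparsity)
            chosen = (sel.chosen_metric, sel.chosen_sparsity)
        else:
            fm = features
            chosen = (None, None)
        model = train_svm(fm.values[train_rows], labels[train_rows], params)
        pred = int(predict(model, fm.values[i])[0])
        folds.append(
            FoldRecord(
                subject_id=subject_ids[i],
                true_label=int(labels[i]),
                predicted_label=pred,
                chosen_metric=chosen[0],
                chosen_sparsity=chosen[1],
            )
        )

    report = performance_metrics(_confusion_from_folds(folds))
    report.folds = folds
    if selection_mode == "paper" and features is not None:
        report.feature_description = (
            f"{features.metric} at sparsity {features.sparsity:.2f} (whole-sample selection)"
        )
    else:
        report.feature_description = "per-fold group-difference selection"
    return report


def performance_metrics(cm: ConfusionMatrix, folds: list[FoldRecord] | None = None) -> PerformanceReport:
    """ACC, sensitivity (SS) and specificity (TNR) from confusion counts."""
    undefined = []
    if cm.total == 0:
        undefined.append("accuracy (no samples)")
    if cm.n_positive == 0:
        undefined.append("sensitivity (no positive samples)")
    if cm.n_negative == 0:
        undefined.append("specificity (no negative samples)")
    if undefined:
        raise ValueError("undefined metric(s): " + "; ".join(undefined))
    acc = (cm.tp + cm.tn) / cm.total
    ss = cm.tp / cm.n_positive
    tnr = cm.tn / cm.n_negative
    return PerformanceReport(
        confusion=cm,
        accuracy=acc,
        sensitivity=ss,
        specificity=tnr,
        folds=folds or [],
    )
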