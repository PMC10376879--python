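"""SVM grading and the per-class evaluation metric suite.

The classifier is a kernel SVM (cubic polynomial by default) on internally
standardized features.  Evaluation collapses the 4x4 confusion matrix
one-vs-rest per grade to obtain TP/TN/FP/FN and reports, per class,

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    recall      = TP / (TP + FN)          (sensitivity)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

alongside the overall multiclass accuracy trace(confusion)/total (the two
"accuracies" are distinct and labelled as such) and one-vs-rest ROC/AUC.
Undefined ratios (empty denominators, plausible for the small severe class)
are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import FeatureTable, Grade

__all__ = [
    "SVMConfig", "ConfusionMatrix", "ClassMetrics", "EvalReport",
    "svm_train", "svm_predict", "evaluate", "f1_from_pr", "report_to_text",
]

N_CLASSES = len(Grade)


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "polynomial"          # linear | polynomial | rbf
    degree: int = 3                     # cubic SVM by default
    regularization: float = 1.0
    multiclass_scheme: str = "one-vs-rest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.multiclass_scheme not in ("one-vs-one", "one-vs-rest"):
            raise ValueError(f"unknown multiclass scheme {self.multiclass_scheme!r}")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")


@dataclass
class ConfusionMatrix:
    """4x4 counts, rows = true grade, columns = predicted grade."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 4x4 with non-negative counts")

    def one_vs_rest(self, grade: Grade) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one grade against all others."""
        g = grade.value
        tp = int(self.counts[g, g])
        fn = int(self.counts[g].sum() - tp)
        fp = int(self.counts[:, g].sum() - tp)
        tn = int(self.counts.sum() - tp - fn - fp)
        return tp, tn, fp, fn


@dataclass
class ClassMetrics:
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    accuracy: float                 # per-class one-vs-rest binary accuracy
    undefined: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    per_class: dict[Grade, ClassMetrics]
    overall_accuracy: float
    roc: dict[Grade, tuple[np.ndarray, np.ndarray]] | None = None   # (FPR, TPR)
    auc: dict[Grade, float] | None = None


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

_KERNEL_MAP = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}


def svm_train(train: FeatureTable, config: SVMConfig | None = None) -> Pipeline:
    """Fit a kernel SVM on internally train-standardized features."""
    config = config or SVMConfig()
    present = np.unique(train.labels)
    if present.size < 2:
        raise ValueError("SVM training needs at least two classes present")
    shape = "ovr" if config.multiclass_scheme == "one-vs-rest" else "ovo"
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(
            kernel=_KERNEL_MAP[config.kernel],
            degree=config.degree,
            C=config.regularization,
            coef0=1.0,
            gamma="scale",
            decision_function_shape=shape,
            random_state=config.seed,
        )),
    ])
    model.fit(train.values, train.labels)
    return model


def svm_predict(model: Pipeline, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Predicted grade codes plus an (n, 4) per-class score matrix.

    Predictions are the argmax of the scores (ties break toward the lower
    grade); classes absent from training score -inf.
    """
    svm: SVC = model.named_steps["svm"]
    expected = svm.shape_fit_[1]
    if table.n_features != expected:
        raise ValueError(f"model expects {expected} features, table has "
                         f"{table.n_features}")
    raw = model.decision_function(table.values)
    classes = svm.classes_
    scores = np.full((table.n_samples, N_CLASSES), -np.inf)
    if raw.ndim == 1:       # binary: signed distance for classes_[1]
        scores[:, classes[0]] = -raw
        scores[:, classes[1]] = raw
    else:
        if svm.decision_function_shape == "ovo" and raw.shape[1] != classes.size:
            # convert pairwise margins to per-class sums
            summed = np.zeros((table.n_samples, classes.size))
            col = 0
            for a in range(classes.size):
                for b in range(a + 1, classes.size):
                    summed[:, a] += raw[:, col]
                    summed[:, b] -= raw[:, col]
                    col += 1
            raw = summed
        for idx, cls in enumerate(classes):
            scores[:, cls] = raw[:, idx]
    return scores.argmax(axis=1), scores


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def evaluate(
    true: Sequence[int] | np.ndarray,
    predicted: Sequence[int] | np.ndarray,
    scores: np.ndarray | None = None,
) -> EvalReport:
    """Confusion matrix, per-class one-vs-rest metrics, and optional ROC/AUC.

    ``scores`` (n x 4, higher = more confident) enables the per-class ROC by
    descending-threshold sweep and trapezoidal AUC; omit it to skip ROC.
    """
    y_true = np.asarray([t.value if isinstance(t, Grade) else int(t) for t in true])
    y_pred = np.asarray([p.value if isinstance(p, Grade) else int(p) for p in predicted])
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted labels differ in length")

    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    confusion = ConfusionMatrix(counts)

    per_class: dict[Grade, ClassMetrics] = {}
    for g in Grade:
        tp, tn, fp, fn = confusion.one_vs_rest(g)
        undefined: list[str] = []
        recall = _ratio(tp, tp + fn, "sensitivity", undefined)
        precision = _ratio(tp, tp + fp, "precision", undefined)
        specificity = _ratio(tn, tn + fp, "specificity", undefined)
        per_class[g] = ClassMetrics(
            sensitivity=recall,
            precision=precision,
            specificity=specificity,
            f1=f1_from_pr(precision, recall),
            accuracy=(tp + tn) / max(tp + tn + fp + fn, 1),
            undefined=undefined,
        )

    roc = aucs = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (y_true.size, N_CLASSES):
            raise ValueError(f"scores must be (n, {N_CLASSES})")
        roc, aucs = {}, {}
        for g in Grade:
            binary = (y_true == g.value).astype(int)
            if binary.min() == binary.max():    # class absent or universal
                roc[g] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
                aucs[g] = 0.0
                continue
            fpr, tpr, _ = _roc_curve(binary, scores[:, g.value])
            roc[g] = (fpr, tpr)
            aucs[g] = float(_auc(fpr, tpr))

    return EvalReport(
        confusion=confusion,
        per_class=per_class,
        overall_accuracy=float(np.trace(counts)) / max(counts.sum(), 1),
        roc=roc,
        auc=aucs,
    )


def report_to_text(report: EvalReport) -> str:
    """Deterministic text rendering (class x metric table + confusion counts)."""
    out = StringIO()
    out.write("confusion matrix (rows true, cols predicted; "
              + "/".join(g.label for g in Grade) + "):\n")
    for g in Grade:
        out.write("  " + " ".join(f"{c:4d}" for c in report.confusion.counts[g.value])
                  + "\n")
    out.write(f"overall accuracy: {report.overall_accuracy:.4f}\n")
    out.write("class      sens    prec    spec      f1  ovr-acc")
    out.write("     auc\n" if report.auc is not None else "\n")
    for g in Grade:
        m = report.per_class[g]
        out.write(f"{g.label:<9} {m.sensitivity:6.4f}  {m.precision:6.4f}  "
                  f"{m.specificity:6.4f}  {m.f1:6.4f}   {m.accuracy:6.4f}")
        if report.auc is not None:
            out.write(f"  {report.auc[g]:6.4f}")
        out.write("\n")
        if m.undefined:
            out.write(f"          (undefined, reported 0: {', '.join(m.undefined)})\n")
    return out.getvalue()
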