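"""Six-kernel SVM classification with group-aware stratified 5-fold CV.

Folds are built at the *patient* level — every lesion of a patient lands in
one fold — stratified by class, so each validation fold keeps both genotypes
represented and fold sizes differ by at most one patient. Metrics follow the
clinical-report convention: per-class precision TP/(TP+FP), sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) with the classes swapping roles for the
negative-class block (so negative-class sensitivity equals positive-class
specificity by construction), plus overall accuracy. Fold summaries are
mean +/- population SD (divisor n_folds). The ROC is computed on decision
values pooled across validation folds, and the AUC by trapezoidal
integration, which equals the tie-corrected pairwise ranking statistic.

Kernel scales for the gaussian variants follow the fine/medium/coarse
convention sqrt(P)/4, sqrt(P), 4*sqrt(P) for P input dimensions; quadratic
and cubic are inhomogeneous polynomial kernels of degree 2 and 3.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

__all__ = [
    "KERNEL_NAMES",
    "KernelSpec",
    "FoldAssignment",
    "FoldMetrics",
    "CVReport",
    "make_folds",
    "build_svc",
    "train_and_score",
    "evaluate_fold",
    "summarize_cv",
    "roc_auc",
]

KERNEL_NAMES = (
    "linear",
    "quadratic",
    "cubic",
    "fine_gaussian",
    "medium_gaussian",
    "coarse_gaussian",
)


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """One of the six SVM kernel variants with its box constraint."""

    name: str
    box_constraint: float = 1.0
    kernel_scale: float | None = None  # gaussian variants; None = by convention

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.kernel_scale is not None and self.kernel_scale <= 0:
            raise ValueError("kernel scale must be > 0")
        if self.box_constraint <= 0:
            raise ValueError("box constraint must be > 0")

    def scale_for(self, n_features: int) -> float | None:
        if self.kernel_scale is not None:
            return self.kernel_scale
        root_p = np.sqrt(n_features)
        return {
            "fine_gaussian": root_p / 4.0,
            "medium_gaussian": root_p,
            "coarse_gaussian": 4.0 * root_p,
        }.get(self.name)


@dataclasses.dataclass
class FoldAssignment:
    """Per-lesion fold index (0-based) with the patient grouping key."""

    fold: np.ndarray
    groups: np.ndarray
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        for g in np.unique(self.groups):
            if len(np.unique(self.fold[self.groups == g])) != 1:
                raise ValueError(f"lesions of patient {g!r} span multiple folds")


@dataclasses.dataclass
class FoldMetrics:
    """Per-class precision/sensitivity/specificity, accuracy, confusion counts."""

    tp: int
    fn: int
    tn: int
    fp: int
    precision_pos: float
    sensitivity_pos: float
    specificity_pos: float
    precision_neg: float
    sensitivity_neg: float
    specificity_neg: float
    accuracy: float
    undefined_precision: bool = False

    def as_row(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class CVReport:
    """Per-fold metrics, mean +/- population-SD summary, pooled ROC and AUC."""

    fold_metrics: list[FoldMetrics]
    summary_mean: dict[str, float]
    summary_sd: dict[str, float]
    pooled_confusion: np.ndarray       # [[TP, FN], [FP, TN]]
    roc_points: np.ndarray             # (n, 2) columns FPR, TPR
    auc: float
    per_fold_auc: list[float]
    mode: str
    seed: int
    kernel: str = ""

    def metrics_frame(self) -> pd.DataFrame:
        cols = [
            "precision_pos", "sensitivity_pos", "specificity_pos",
            "precision_neg", "sensitivity_neg", "specificity_neg", "accuracy",
        ]
        df = pd.DataFrame([m.as_row() for m in self.fold_metrics])
        df.index = [f"fold{i + 1}" for i in range(len(self.fold_metrics))]
        out = df[cols].copy()
        out.loc["mean"] = [self.summary_mean[c] for c in cols]
        out.loc["sd"] = [self.summary_sd[c] for c in cols]
        return out


def make_folds(
    labels: np.ndarray, groups: np.ndarray, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Patient-level stratified fold assignment.

    Patients are shuffled with the seed and dealt class-by-class to the fold
    currently holding the fewest patients of that class (ties broken by total
    fold size, then fold index), so class representation is as even as
    feasible and fold sizes differ by at most one patient.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    patient_ids, first_idx = np.unique(groups, return_index=True)
    if len(patient_ids) < k:
        raise ValueError(f"need at least {k} patients, got {len(patient_ids)}")
    patient_label = {g: labels[i] for g, i in zip(patient_ids, first_idx)}

    rng = np.random.default_rng(seed)
    order = patient_ids[rng.permutation(len(patient_ids))]

    class_counts = np.zeros((k, 2), dtype=int)
    assignment: dict = {}
    for cls in (1, 0):  # positives dealt first; order is immaterial to balance
        for g in order:
            if patient_label[g] != cls:
                continue
            totals = class_counts.sum(axis=1)
            # lexicographic: fewest of this class, then fewest total, then index
            key = class_counts[:, cls] * 10**6 + totals * 10**3 + np.arange(k)
            fold = int(np.argmin(key))
            assignment[g] = fold
            class_counts[fold, cls] += 1

    fold = np.array([assignment[g] for g in groups])
    return FoldAssignment(fold=fold, groups=groups, labels=labels, k=k)


def build_svc(kernel: KernelSpec, n_features: int) -> SVC:
    c = kernel.box_constraint
    if kernel.name == "linear":
        return SVC(kernel="linear", C=c)
    if kernel.name in ("quadratic", "cubic"):
        degree = 2 if kernel.name == "quadratic" else 3
        return SVC(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=c)
    scale = kernel.scale_for(n_features)
    return SVC(kernel="rbf", gamma=1.0 / scale**2, C=c)


def train_and_score(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    kernel: KernelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a soft-margin SVM and score the test lesions.

    Returns ``(decision_values, predicted_labels)``; positive decision values
    point to the BRAF-positive class and the natural threshold 0 is used
    (no threshold tuning). Deterministic for fixed inputs.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    clf = build_svc(kernel, x_train.shape[1])
    clf.fit(x_train, y_train)
    decision = clf.decision_function(x_test)
    if list(clf.classes_) == [1, 0]:  # ensure positive class on the + side
        decision = -decision
    return decision, (decision > 0).astype(int)


def evaluate_fold(predicted: np.ndarray, truth: np.ndarray) -> FoldMetrics:
    """Confusion counts and per-class metrics for one validation fold.

    A class that is never predicted has undefined (0/0) precision; it is
    reported as 0 with the ``undefined_precision`` flag set.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0 or predicted.shape != truth.shape:
        raise ValueError("predicted and truth must be equal-length and nonempty")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())

    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    undefined = (tp + fp == 0) or (tn + fn == 0)
    if undefined:
        warnings.warn("a class was never predicted; its precision is reported as 0",
                      stacklevel=2)
    sensitivity_pos = _ratio(tp, tp + fn)
    specificity_pos = _ratio(tn, tn + fp)
    return FoldMetrics(
        tp=tp, fn=fn, tn=tn, fp=fp,
        precision_pos=_ratio(tp, tp + fp),
        sensitivity_pos=sensitivity_pos,
        specificity_pos=specificity_pos,
        precision_neg=_ratio(tn, tn + fn),
        sensitivity_neg=specificity_pos,   # classes swap roles
        specificity_neg=sensitivity_pos,
        accuracy=(tp + tn) / predicted.size,
        undefined_precision=undefined,
    )


def roc_auc(decision_values: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep and the trapezoidal AUC.

    Equivalent to the pairwise ranking statistic: the fraction of
    (positive, negative) pairs ranked correctly, ties counting 1/2.
    """
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present in the truth labels")
    fpr, tpr, _ = roc_curve(truth, decision_values, pos_label=1,
                            drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def summarize_cv(
    fold_metrics: list[FoldMetrics],
    pooled_decision: np.ndarray | None = None,
    pooled_truth: np.ndarray | None = None,
    per_fold_auc: list[float] | None = None,
    mode: str = "whole_cohort",
    seed: int = 0,
    kernel: str = "",
) -> CVReport:
    """Mean and population-SD fold summaries plus the pooled ROC/AUC.

    The SD uses divisor n_folds (population convention). When no pooled
    decision values are supplied the ROC block is empty and AUC is NaN.
    """
    if len(fold_metrics) < 2:
        raise ValueError("need at least 2 folds to summarize")
    cols = [
        "precision_pos", "sensitivity_pos", "specificity_pos",
        "precision_neg", "sensitivity_neg", "specificity_neg", "accuracy",
    ]
    arr = {c: np.array([getattr(m, c) for m in fold_metrics]) for c in cols}
    summary_mean = {c: float(v.mean()) for c, v in arr.items()}
    summary_sd = {c: float(v.std(ddof=0)) for c, v in arr.items()}

    confusion = np.array(
        [
            [sum(m.tp for m in fold_metrics), sum(m.fn for m in fold_metrics)],
            [sum(m.fp for m in fold_metrics), sum(m.tn for m in fold_metrics)],
        ]
    )
    if pooled_decision is not None and pooled_truth is not None:
        roc_points, auc = roc_auc(pooled_decision, pooled_truth)
    else:
        roc_points, auc = np.empty((0, 2)), float("nan")
    return CVReport(
        fold_metrics=fold_metrics,
        summary_mean=summary_mean,
        summary_sd=summary_sd,
        pooled_confusion=confusion,
        roc_points=roc_points,
        auc=auc,
        per_fold_auc=per_fold_auc or [],
        mode=mode,
        seed=seed,
        kernel=kernel,
    )
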