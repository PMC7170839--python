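"""Model/Results interface for the radiomics genotype classifier.

:class:`VirtualBiopsyModel` is built from a lesions-by-features table plus
binary BRAF labels and patient grouping keys; :meth:`VirtualBiopsyModel.fit`
runs the screening -> standardization -> PCA -> SVM cross-validation chain and
returns a :class:`VirtualBiopsyResults` carrying the per-fold metrics, their
mean +/- SD summary, the pooled ROC/AUC, the selection report and the PCA
transform, with a ``summary()`` table in the usual statistical-modelling
style.

Two evaluation modes exist:

* ``"whole_cohort"`` — feature screening, standardization and PCA are fit
  once on the whole cohort before cross-validation, as in the original
  analysis. The fold metrics then inherit the optimism of that shared
  preprocessing (selection has seen the validation labels).
* ``"leakage_free"`` — all three steps are refit inside each training fold
  and applied frozen to the validation fold; this is the unbiased estimate
  of generalization performance.

Reports always state the mode.
"""

from __future__ import annotations

import dataclasses
import io as _io

import numpy as np
import pandas as pd

from .classify import (
    CVReport,
    FoldMetrics,
    KernelSpec,
    evaluate_fold,
    make_folds,
    roc_auc,
    summarize_cv,
    train_and_score,
)
from .selection import PCATransform, SelectionReport, fit_pca, select_features, standardize

__all__ = ["VirtualBiopsyModel", "VirtualBiopsyResults", "cross_validate"]

MODES = ("whole_cohort", "leakage_free")


def _fit_preprocessing(
    features: pd.DataFrame,
    labels: np.ndarray,
    alpha: float,
    variance_threshold: float,
) -> tuple[SelectionReport, PCATransform]:
    """Screen, standardize and rotate; shared by both evaluation modes."""
    report = select_features(features, labels, alpha=alpha)
    selected = report.selected
    if not selected:
        # never leave the classifier without input: fall back to the single
        # most discriminative feature
        finite = report.table.dropna(subset=["p_value"])
        if finite.empty:
            raise ValueError("no usable features: all constant or non-finite")
        selected = [finite.sort_values("p_value").iloc[0]["feature"]]
    sub = features[selected]
    z, means, sds = standardize(sub)
    if z.shape[1] < 2:
        # PCA needs >= 2 columns; degenerate selections pass through unrotated
        pca = PCATransform(
            feature_names=list(z.columns),
            means=means.to_numpy(),
            sds=sds.to_numpy(),
            loadings=np.eye(z.shape[1]),
            explained_variance_ratio=np.ones(z.shape[1]),
            k=z.shape[1],
            variance_threshold=variance_threshold,
        )
    else:
        pca = fit_pca(z, variance_threshold, means=means, sds=sds)
    return report, pca


def cross_validate(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    kernel: KernelSpec,
    k: int = 5,
    seed: int = 0,
    mode: str = "whole_cohort",
    alpha: float = 0.05,
    variance_threshold: float = 0.95,
) -> tuple[CVReport, SelectionReport | None, PCATransform | None]:
    """Group-aware stratified k-fold CV of the full pipeline.

    Returns the CV report plus, in whole-cohort mode, the cohort-level
    selection report and PCA transform (in leakage-free mode these are
    refit per fold and None is returned).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    labels = np.asarray(labels)
    folds = make_folds(labels, groups, k=k, seed=seed)

    report = pca = None
    if mode == "whole_cohort":
        report, pca = _fit_preprocessing(features, labels, alpha, variance_threshold)
        scores = pca.transform(features)

    fold_metrics: list[FoldMetrics] = []
    pooled_decision: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    per_fold_auc: list[float] = []
    for f in range(k):
        test = folds.fold == f
        train = ~test
        if mode == "whole_cohort":
            x_train, x_test = scores[train], scores[test]
        else:
            _, fold_pca = _fit_preprocessing(
                features.loc[train], labels[train], alpha, variance_threshold
            )
            x_train = fold_pca.transform(features.loc[train])
            x_test = fold_pca.transform(features.loc[test])
        decision, predicted = train_and_score(x_train, labels[train], x_test, kernel)
        fold_metrics.append(evaluate_fold(predicted, labels[test]))
        pooled_decision.append(decision)
        pooled_truth.append(labels[test])
        if len(np.unique(labels[test])) == 2:
            _, fauc = roc_auc(decision, labels[test])
            per_fold_auc.append(fauc)
        else:
            per_fold_auc.append(float("nan"))

    cv = summarize_cv(
        fold_metrics,
        np.concatenate(pooled_decision),
        np.concatenate(pooled_truth),
        per_fold_auc=per_fold_auc,
        mode=mode,
        seed=seed,
        kernel=kernel.name,
    )
    return cv, report, pca


class VirtualBiopsyModel:
    """Radiomics-based BRAF-status classifier for one cohort.

    Parameters
    ----------
    features : DataFrame, lesions x features (the 195-feature table or any
        subset; non-numeric columns are rejected).
    labels : binary array, 1 = BRAF-positive.
    groups : patient identifiers (lesions of one patient are never split
        across CV folds); defaults to one patient per lesion.
    alpha : univariate screening level (default 0.05).
    variance_threshold : cumulative explained-variance cut for PCA (0.95).
    mode : "whole_cohort" or "leakage_free".
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray,
        groups: np.ndarray | None = None,
        alpha: float = 0.05,
        variance_threshold: float = 0.95,
        mode: str = "whole_cohort",
    ) -> None:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.features = features.astype(np.float64)
        self.labels = np.asarray(labels).astype(int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")
        self.groups = (
            np.asarray(groups) if groups is not None else np.arange(len(self.labels))
        )
        self.alpha = alpha
        self.variance_threshold = variance_threshold
        self.mode = mode

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_column: str = "braf_status",
        group_column: str | None = "subject_id",
        **kwargs,
    ) -> "VirtualBiopsyModel":
        """Build from one table that mixes features with label/group columns."""
        labels = frame[label_column]
        if labels.dtype == object:
            labels = (labels == "positive").astype(int)
        drop = [label_column]
        groups = None
        if group_column and group_column in frame.columns:
            groups = frame[group_column].to_numpy()
            drop.append(group_column)
        features = frame.drop(columns=drop)
        return cls(features, labels.to_numpy(), groups=groups, **kwargs)

    def fit(
        self,
        kernel: str | KernelSpec = "linear",
        n_folds: int = 5,
        seed: int = 0,
    ) -> "VirtualBiopsyResults":
        """Cross-validate the pipeline and return the results object."""
        spec = kernel if isinstance(kernel, KernelSpec) else KernelSpec(name=kernel)
        cv, report, pca = cross_validate(
            self.features,
            self.labels,
            self.groups,
            spec,
            k=n_folds,
            seed=seed,
            mode=self.mode,
            alpha=self.alpha,
            variance_threshold=self.variance_threshold,
        )
        return VirtualBiopsyResults(model=self, kernel=spec, cv_report=cv,
                                    selection=report, pca=pca)


@dataclasses.dataclass
class VirtualBiopsyResults:
    """Cross-validated performance of one kernel on one cohort."""

    model: VirtualBiopsyModel
    kernel: KernelSpec
    cv_report: CVReport
    selection: SelectionReport | None
    pca: PCATransform | None

    @property
    def auc(self) -> float:
        return self.cv_report.auc

    @property
    def mean_accuracy(self) -> float:
        return self.cv_report.summary_mean["accuracy"]

    def summary(self) -> str:
        """Plain-text report: per-fold metrics, mean +/- SD, AUC, mode."""
        cv = self.cv_report
        buf = _io.StringIO()
        buf.write("Virtual biopsy: BRAF-status SVM cross-validation\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"kernel: {self.kernel.name}    folds: {len(cv.fold_metrics)}")
        buf.write(f"    mode: {cv.mode}    seed: {cv.seed}\n")
        n_pos = int(self.model.labels.sum())
        n_neg = int(len(self.model.labels) - n_pos)
        buf.write(f"lesions: {len(self.model.labels)} ({n_pos} positive / {n_neg} negative)\n")
        if self.selection is not None:
            buf.write(
                f"features selected: {len(self.selection.selected)}"
                f"/{len(self.selection.table)} at p < {self.selection.alpha:g}\n"
            )
        if self.pca is not None:
            buf.write(
                f"PCA components: {self.pca.k} "
                f"(>= {self.pca.variance_threshold:.0%} cumulative variance)\n"
            )
        buf.write("-" * 60 + "\n")
        buf.write(cv.metrics_frame().to_string(float_format=lambda v: f"{v:.3f}"))
        buf.write("\n" + "-" * 60 + "\n")
        buf.write(f"pooled ROC AUC (positive BRAF): {cv.auc:.3f}\n")
        tp, fn = cv.pooled_confusion[0]
        fp, tn = cv.pooled_confusion[1]
        buf.write(f"pooled confusion: TP={tp} FN={fn} FP={fp} TN={tn}\n")
        return buf.getvalue()

    def plot_roc(self, ax=None):
        """Pooled ROC curve; returns the matplotlib axes."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pts = self.cv_report.roc_points
        ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post",
                label=f"{self.kernel.name} (AUC = {self.cv_report.auc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
        ax.set_xlabel("False-positive rate")
        ax.set_ylabel("True-positive rate")
        ax.set_title(f"BRAF-positive prediction ({self.cv_report.mode})")
        ax.legend(loc="lower right", frameon=False)
        return ax
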