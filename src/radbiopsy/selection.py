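"""Univariate two-group screening, standardization, and PCA reduction.

Each of the 195 features is tested for a difference between BRAF-positive and
BRAF-negative lesions: a one-sample Kolmogorov-Smirnov test on the z-scored
values decides, per group, whether the feature looks normal; a pooled-variance
two-sample t-test is used when both groups pass, otherwise the Mann-Whitney U
test (tie-corrected normal approximation, no continuity correction). Features
with p < alpha (default 0.05, no multiplicity correction) are retained,
standardized to zero mean / unit sample SD over the whole cohort, and rotated
by PCA; the smallest number of components whose cumulative explained variance
reaches the threshold (default 95%) is kept.

An optional Benjamini-Hochberg correction is available but off by default,
matching the uncorrected screening of the original analysis.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionReport",
    "PCATransform",
    "test_normality",
    "group_difference_test",
    "select_features",
    "standardize",
    "fit_pca",
]


@dataclasses.dataclass
class SelectionReport:
    """Per-feature test choice and p-value, plus the selected subset."""

    table: pd.DataFrame  # feature, normal_pos, normal_neg, test, p_value, selected
    alpha: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "feature"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


@dataclasses.dataclass
class PCATransform:
    """Standardization constants plus component loadings.

    ``transform`` maps raw feature rows to the first ``k`` principal-component
    scores, standardizing with the stored cohort constants first. ``k`` is the
    smallest component count whose cumulative explained variance reaches
    ``variance_threshold``.
    """

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray               # features x all retained components
    explained_variance_ratio: np.ndarray
    k: int
    variance_threshold: float

    def transform(self, table: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
        k = self.k if n_components is None else n_components
        x = table[self.feature_names].to_numpy(dtype=np.float64)
        z = (x - self.means) / self.sds
        return z @ self.loadings[:, :k]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.loadings,
            index=self.feature_names,
            columns=[f"PC{i + 1}" for i in range(self.loadings.shape[1])],
        )
        df.insert(0, "mean", self.means)
        df.insert(1, "sd", self.sds)
        df.to_csv(path, float_format="%.12g", index_label="feature")


def test_normality(values: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """One-sample KS test of the z-scored values against the standard normal.

    Returns ``(is_normal, p)``. Fewer than 3 finite values or zero spread give
    a "non-normal" verdict with a NaN sentinel p (the z-scoring is undefined).
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.std(ddof=1) == 0:
        return False, float("nan")
    z = (x - x.mean()) / x.std(ddof=1)
    p = float(stats.kstest(z, "norm").pvalue)
    return p >= alpha, p


def group_difference_test(
    values_pos: np.ndarray, values_neg: np.ndarray, normality_alpha: float = 0.05
) -> tuple[float, str]:
    """Two-sided p-value for a location difference between the two groups.

    Pooled-variance t-test when both groups pass the KS normality gate;
    otherwise Mann-Whitney U with the tie-corrected normal approximation
    (no continuity correction, so identical samples give p = 1).
    """
    a = np.asarray(values_pos, dtype=np.float64)
    b = np.asarray(values_neg, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    normal_a, _ = test_normality(a, normality_alpha)
    normal_b, _ = test_normality(b, normality_alpha)
    if normal_a and normal_b:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        return p, "t-test"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-identical inputs warn harmlessly
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.pvalue), "mann-whitney"


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    fdr: bool = False,
) -> SelectionReport:
    """Screen every feature column for a class difference at level ``alpha``.

    ``labels`` are 1 (positive) / 0 (negative). Constant or non-finite
    features are skipped (never selected, p = NaN). ``fdr`` switches on a
    Benjamini-Hochberg correction of the p-values before thresholding.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos = labels == 1
    rows = []
    for feat in table.columns:
        x = table[feat].to_numpy(dtype=np.float64)
        if not np.isfinite(x).all() or np.ptp(x) == 0:
            rows.append((feat, False, False, "skipped", float("nan")))
            continue
        a, b = x[pos], x[~pos]
        normal_a, _ = test_normality(a)
        normal_b, _ = test_normality(b)
        p, test = group_difference_test(a, b)
        rows.append((feat, normal_a, normal_b, test, p))
    df = pd.DataFrame(rows, columns=["feature", "normal_pos", "normal_neg", "test", "p_value"])
    pvals = df["p_value"].to_numpy()
    if fdr:
        ok = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(pvals[ok], method="bh")
        df["p_adjusted"] = adj
        df["selected"] = adj < alpha
    else:
        df["selected"] = pvals < alpha
    df["selected"] = df["selected"].fillna(False)
    return SelectionReport(table=df, alpha=alpha)


def standardize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center each feature on the cohort mean and scale to unit sample SD.

    Returns ``(standardized, means, sds)``; zero-spread columns are dropped
    with a warning (their z-scores are undefined).
    """
    means = table.mean()
    sds = table.std(ddof=1)
    bad = sds[sds == 0].index.tolist()
    if bad:
        warnings.warn(f"dropping zero-spread features before PCA: {bad}", stacklevel=2)
        table = table.drop(columns=bad)
        means = means.drop(bad)
        sds = sds.drop(bad)
    z = (table - means) / sds
    return z, means, sds


def fit_pca(standardized: pd.DataFrame, variance_threshold: float = 0.95,
            means: pd.Series | None = None, sds: pd.Series | None = None) -> PCATransform:
    """Eigendecomposition of the feature covariance of the standardized table.

    Near-zero eigenvalues (< 1e-12 of the total) are discarded as numerical
    rank deficiency. Component signs are fixed by making each component's
    largest-magnitude loading positive, so identical inputs give identical
    transforms.
    """
    if standardized.shape[1] < 2:
        raise ValueError("need at least 2 features for PCA")
    if standardized.shape[0] < 3:
        raise ValueError("need at least 3 lesions for PCA")
    x = np.ascontiguousarray(standardized.to_numpy(dtype=np.float64))
    cov = np.cov(x, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    total = eigvals.sum()
    keep = eigvals > 1e-12 * total
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    # sign convention: largest-magnitude loading positive
    for c in range(eigvecs.shape[1]):
        peak = np.argmax(np.abs(eigvecs[:, c]))
        if eigvecs[peak, c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    evr = eigvals / eigvals.sum()
    k = int(np.searchsorted(np.cumsum(evr), variance_threshold) + 1)
    k = min(k, len(evr))
    names = list(standardized.columns)
    means_arr = (means.reindex(names).to_numpy() if means is not None
                 else np.zeros(len(names)))
    sds_arr = (sds.reindex(names).to_numpy() if sds is not None
               else np.ones(len(names)))
    return PCATransform(
        feature_names=names,
        means=means_arr,
        sds=sds_arr,
        loadings=eigvecs,
        explained_variance_ratio=evr,
        k=k,
        variance_threshold=variance_threshold,
    )
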