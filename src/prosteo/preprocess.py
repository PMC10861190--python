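"""Protein-matrix preprocessing and screening statistics.

Half-minimum imputation for left-censored abundances, column z-standardization
with reusable parameters, T-score classification of BMD, fold-change screening
with Benjamini-Hochberg control, a PCA batch check, and the paired t test used
for the within-person BMD change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "HalfMinImputer",
    "ProteinStandardizer",
    "impute_half_min",
    "standardize",
    "tscore",
    "tscore_classify",
    "fold_change",
    "bh_adjust",
    "pca_batch_check",
    "paired_t",
]


class HalfMinImputer(TransformerMixin, BaseEstimator):
    """Impute left-censored missing abundances with half the observed minimum.

    The per-column minimum is learned on the data passed to :meth:`fit`
    (typically all analyzed samples pooled across visits) and each missing cell
    of column *j* is replaced with ``min_observed(j) / 2``.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "HalfMinImputer":
        X = _as_frame(X)
        fully_missing = X.columns[X.isna().all(axis=0)]
        if len(fully_missing) > 0:
            raise ValueError(
                f"cannot impute fully missing protein column(s): {list(fully_missing)}"
            )
        self.fill_values_ = X.min(axis=0, skipna=True) / 2.0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _as_frame(X)
        return X.fillna(self.fill_values_)


class ProteinStandardizer(TransformerMixin, BaseEstimator):
    """Column z-standardization with the fit/apply split made explicit.

    Means and standard deviations (ddof=1) are computed on the rows passed to
    :meth:`fit` and applied unchanged by :meth:`transform`, so follow-up visits
    or a held-out batch can be scaled with baseline parameters without leakage.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "ProteinStandardizer":
        X = _as_frame(X)
        if X.isna().any().any():
            raise ValueError("standardize requires an imputed (complete) matrix")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero_var = sd.index[(sd == 0) | sd.isna()]
        if len(zero_var) > 0:
            raise ValueError(f"zero-variance column(s): {list(zero_var)}")
        self.mean_ = mean
        self.scale_ = sd
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _as_frame(X)
        return (X - self.mean_) / self.scale_


def impute_half_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Functional form of :class:`HalfMinImputer` (fit and apply on ``matrix``)."""
    return HalfMinImputer().fit_transform(matrix)


def standardize(
    matrix: pd.DataFrame, fit_on: Sequence | pd.Index | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-standardize columns, fitting mean/sd on ``fit_on`` rows (default: all).

    Returns the transformed matrix and a (mean, sd) parameter frame for reuse.
    """
    scaler = ProteinStandardizer()
    fit_rows = matrix if fit_on is None else matrix.loc[fit_on]
    scaler.fit(fit_rows)
    params = pd.DataFrame({"mean": scaler.mean_, "sd": scaler.scale_})
    return scaler.transform(matrix), params


def tscore(bmd: float, ref_mean: float, ref_sd: float) -> float:
    if ref_sd <= 0:
        raise ValueError("ref_sd must be > 0")
    return (bmd - ref_mean) / ref_sd


def tscore_classify(
    bmd,
    ref_mean: float,
    ref_sd: float,
    treated: bool | np.ndarray = False,
):
    """Classify BMD into normal / osteopenia / osteoporosis by T-score.

    The partition is total: osteoporosis for T < -2.5, osteopenia for
    -2.5 <= T < -1, normal for T >= -1. Participants currently under medical
    treatment for osteoporosis (``treated``) are classified osteoporotic
    regardless of T.

    Accepts scalars or arrays; returns ``(T, status)`` with matching shape.
    """
    t = np.asarray(tscore(np.asarray(bmd, dtype=float), ref_mean, ref_sd))
    status = np.where(t < -2.5, "osteoporosis", np.where(t < -1.0, "osteopenia", "normal"))
    status = np.where(np.asarray(treated, dtype=bool), "osteoporosis", status)
    if np.isscalar(bmd) or np.asarray(bmd).ndim == 0:
        return float(t), str(status if status.ndim == 0 else status.item())
    return t, status


@dataclass
class FoldChangeRow:
    protein: str
    fc: float
    p: float
    q: float = np.nan


def fold_change(
    matrix: pd.DataFrame,
    case_rows,
    control_rows,
    test: Literal["welch", "wilcoxon"] = "welch",
) -> pd.DataFrame:
    """Per-protein fold change between cases and controls with BH-adjusted p.

    ``FC = (mean_case - mean_control) / mean_control`` on imputed,
    *unstandardized* abundances (a zero control mean would make FC undefined on
    centered data). The group-difference p-value comes from a two-sided Welch
    t test by default (Mann-Whitney available via ``test="wilcoxon"``).
    """
    cases = matrix.loc[case_rows]
    controls = matrix.loc[control_rows]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    mean_case = cases.mean(axis=0)
    mean_ctrl = controls.mean(axis=0)
    if (mean_ctrl == 0).any():
        bad = list(mean_ctrl.index[mean_ctrl == 0])
        raise ValueError(f"control mean is 0 (FC undefined); use raw abundances: {bad}")
    fc = (mean_case - mean_ctrl) / mean_ctrl
    if test == "welch":
        res = stats.ttest_ind(cases, controls, equal_var=False, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    elif test == "wilcoxon":
        p = np.array(
            [
                stats.mannwhitneyu(cases[c].dropna(), controls[c].dropna()).pvalue
                for c in matrix.columns
            ]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    # identical groups give 0/0 in the t statistic; the difference is exactly
    # null so report p = 1
    p = np.where(np.isnan(p) & (fc.to_numpy() == 0), 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame({"protein": matrix.columns, "fc": fc.to_numpy(), "p": p, "q": q})


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q(i) = min_{j >= i} min(1, m * p(j) / j)`` over the sorted p-values;
    input order is preserved in the output.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pca_batch_check(
    matrix: pd.DataFrame, batch_labels: Sequence, n_components: int = 10
) -> dict:
    """Principal components of a standardized matrix plus a batch-separation summary.

    Returns the variance explained per component, its cumulative sum, and the
    absolute difference of batch means on PC1 in units of the PC1 SD (NaN when
    only one batch is present).
    """
    X = _as_frame(matrix)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    labels = np.asarray(batch_labels)
    out = {
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "cumulative_variance": np.cumsum(pca.explained_variance_ratio_),
        "pc_scores": scores,
    }
    uniq = np.unique(labels)
    if len(uniq) >= 2:
        pc1 = scores[:, 0]
        sd = pc1.std(ddof=1)
        means = [pc1[labels == u].mean() for u in uniq[:2]]
        out["pc1_batch_gap_sd"] = abs(means[0] - means[1]) / sd if sd > 0 else 0.0
    else:
        out["pc1_batch_gap_sd"] = np.nan
    return out


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired t test: one-sample t on within-pair differences, two-sided p.

    Returns ``(t, df, p)``. Zero-variance differences with a nonzero mean are a
    degenerate case: t is infinite and p is reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.inf * np.sign(d.mean())), df, 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))
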