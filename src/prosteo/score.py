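"""Protein risk score (PRS) construction and cross-sectional association.

The PRS is the meta-analysis-weighted sum of standardized protein abundances,
``raw_i = sum_j w_j z_ij``, with weights oriented to a risk scale (positive
weight = BMD-lowering protein) so hazard ratios above 1 are expected for higher
scores. Scores are z-standardized over the scoring set and can be handled
continuously or as quartiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ProteinRiskScore", "build_prs", "prs_quartiles", "fit_glm_cross"]


class ProteinRiskScore(TransformerMixin, BaseEstimator):
    """Weighted protein score with risk orientation and z-standardization.

    Parameters
    ----------
    weights : mapping protein -> weight
        Typically pooled meta-analysis betas of BMD on protein (BMD-SD per
        protein-SD).
    orient_to_risk : bool
        When True (default), weights are sign-flipped so that a positive weight
        means BMD-lowering: the stored weights are ``-beta`` for betas measured
        on the BMD scale.
    """

    def __init__(self, weights: dict | pd.Series, orient_to_risk: bool = True):
        self.weights = weights
        self.orient_to_risk = orient_to_risk

    def fit(self, X: pd.DataFrame, y=None) -> "ProteinRiskScore":
        w = pd.Series(self.weights, dtype=float)
        if len(w) == 0 or (w == 0).all():
            raise ValueError("degenerate score: all weights are zero")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        missing = [c for c in w.index if c not in X.columns]
        if missing:
            raise ValueError(f"weighted protein(s) missing from matrix: {missing}")
        self.weights_ = -w if self.orient_to_risk else w.copy()
        raw = X[self.weights_.index].to_numpy() @ self.weights_.to_numpy()
        self.raw_mean_ = float(raw.mean())
        self.raw_sd_ = float(raw.std(ddof=1))
        if self.raw_sd_ == 0:
            raise ValueError("degenerate score: zero variance on the fitting set")
        return self

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.weights_.index if c not in X.columns]
        if missing:
            raise ValueError(f"weighted protein(s) missing from matrix: {missing}")
        return X[self.weights_.index].to_numpy() @ self.weights_.to_numpy()

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return (self.raw_scores(X) - self.raw_mean_) / self.raw_sd_


def build_prs(
    weights: dict | pd.Series, matrix: pd.DataFrame, orient_to_risk: bool = True
) -> pd.DataFrame:
    """Score a standardized protein matrix with meta-analysis weights.

    Returns a frame indexed like ``matrix`` with ``raw`` and ``standardized``
    columns (standardization over the scoring set itself).
    """
    scorer = ProteinRiskScore(weights, orient_to_risk=orient_to_risk).fit(matrix)
    raw = scorer.raw_scores(matrix)
    return pd.DataFrame(
        {"raw": raw, "standardized": (raw - raw.mean()) / raw.std(ddof=1)},
        index=matrix.index,
    )


def prs_quartiles(scores) -> tuple[np.ndarray, bool]:
    """Quartile labels 1-4 at the 25/50/75 sample percentiles.

    Ties are broken by stable rank order so the partition is always total.
    Returns ``(labels, degenerate)``; ``degenerate`` is True when the cuts
    collapse (e.g. all scores equal), in which case everything lands in Q1.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 scores for quartiles")
    ranks = stats.rankdata(s, method="ordinal")  # stable tie-break
    labels = np.ceil(ranks * 4 / s.size).astype(int)
    degenerate = len(np.unique(np.percentile(s, [25, 50, 75]))) < 3
    if degenerate and np.all(s == s[0]):
        labels = np.ones_like(labels)
    return labels, degenerate


def fit_glm_cross(
    prs,
    outcome,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
) -> dict:
    """Cross-sectional GLM of an outcome on the PRS with covariate adjustment.

    ``family="linear"`` returns the BMD coefficient per SD of PRS;
    ``family="logistic"`` returns the log-odds coefficient and its exponential
    as an odds ratio. Wald 95% CI and p throughout.
    """
    import statsmodels.api as sm

    prs = np.asarray(prs, dtype=float)
    y = np.asarray(outcome, dtype=float)
    X = prs.reshape(-1, 1)
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    X = sm.add_constant(X)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X[keep], y[keep]
    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "logistic":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("logistic family needs a binary outcome")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception as exc:
                raise RuntimeError(f"logistic fit failed (separation?): {exc}") from exc
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge (possible separation)")
    else:
        raise ValueError(f"unknown family {family!r}")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    ci = (beta - 1.959963984540054 * se, beta + 1.959963984540054 * se)
    out = {
        "beta": beta,
        "se": se,
        "ci": ci,
        "p": float(fit.pvalues[1]),
        "n": int(keep.sum()),
        "family": family,
    }
    if family == "logistic":
        out["or"] = float(np.exp(beta))
        out["or_ci"] = (float(np.exp(ci[0])), float(np.exp(ci[1])))
    return out
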