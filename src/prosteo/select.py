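"""Protein selection for osteoporosis classification.

Two selectors operate on baseline protein z-scores with an ever-osteoporosis
label: a gradient-boosted tree classifier keeping features whose mean absolute
SHAP attribution exceeds zero, and an L1-penalized logistic regression with the
penalty chosen by cross-validated deviance. Discrimination is summarized with
the Mann-Whitney (rank) formulation of the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegressionCV

__all__ = [
    "SelectionResult",
    "split_discovery",
    "ShapSelector",
    "LassoSelector",
    "select_by_shap",
    "select_by_lasso",
    "auc",
]

#: tolerance absorbing floating-point attribution noise in the |SHAP| > 0 rule
SHAP_TOL = 1e-12


@dataclass
class SelectionResult:
    method: str  # "gbm_shap" | "lasso"
    retained: list
    importance: pd.Series  # per-feature mean |SHAP| or |coefficient|
    auc_train: float = np.nan
    auc_test: float = np.nan
    auc_validation: float = np.nan
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.importance.index,
                "importance": self.importance.to_numpy(),
                "retained": [p in set(self.retained) for p in self.importance.index],
            }
        )


def split_discovery(rows: pd.Index | np.ndarray, train_frac: float, seed: int):
    """Randomly split row ids into disjoint, exhaustive train/test sets.

    The training size is ``round(n * train_frac)``; deterministic given seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rows = np.asarray(rows)
    n = rows.size
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_frac))
    return rows[np.sort(perm[:n_train])], rows[np.sort(perm[n_train:])]


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    return X, y


class ShapSelector(BaseEstimator):
    """Gradient-boosted tree classifier with mean-|SHAP| feature selection.

    A LightGBM binary classifier is fitted on the training rows; per-feature
    TreeSHAP attributions are computed on the same rows and features with mean
    absolute attribution above zero (tolerance ``SHAP_TOL``) are retained.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        num_leaves: int = 15,
        learning_rate: float = 0.05,
        min_child_samples: int = 20,
        seed: int = 0,
    ):
        self.n_estimators = n_estimators
        self.num_leaves = num_leaves
        self.learning_rate = learning_rate
        self.min_child_samples = min_child_samples
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "ShapSelector":
        X, y = _check_xy(X, y)
        model = lgb.LGBMClassifier(
            n_estimators=self.n_estimators,
            num_leaves=self.num_leaves,
            learning_rate=self.learning_rate,
            min_child_samples=self.min_child_samples,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
        model.fit(X, y)
        # LightGBM ships TreeSHAP: pred_contrib returns per-feature attributions
        # plus a bias column (dropped)
        contrib = model.predict(X, pred_contrib=True)[:, :-1]
        mean_abs = np.abs(contrib).mean(axis=0)
        self.model_ = model
        self.importances_ = pd.Series(mean_abs, index=X.columns)
        self.support_ = self.importances_ > SHAP_TOL
        self.retained_ = list(self.importances_.index[self.support_])
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(X)

    def decision_scores(self, X) -> np.ndarray:
        return self.model_.predict_proba(X)[:, 1]


class LassoSelector(BaseEstimator):
    """L1-penalized logistic regression with cross-validated penalty choice.

    The regularization path is scored by n-fold cross-validated deviance
    (negative log-loss); features with nonzero coefficients at the selected
    penalty are retained.
    """

    def __init__(self, n_folds: int = 10, n_lambdas: int = 30, seed: int = 0):
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "LassoSelector":
        X, y = _check_xy(X, y)
        if self.n_folds > len(y):
            raise ValueError("n_folds exceeds the number of samples")
        model = LogisticRegressionCV(
            Cs=self.n_lambdas,
            cv=self.n_folds,
            l1_ratios=(1.0,),
            solver="saga",
            scoring="neg_log_loss",
            random_state=self.seed,
            max_iter=5000,
            use_legacy_attributes=False,
        )
        model.fit(X, y)
        coefs = np.abs(model.coef_.ravel())
        self.model_ = model
        self.importances_ = pd.Series(coefs, index=X.columns)
        self.support_ = self.importances_ > 0
        self.retained_ = list(self.importances_.index[self.support_])
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self.model_.predict_proba(X)[:, 1]


def _evaluate(selector, method, X_train, y_train, X_test=None, y_test=None,
              X_val=None, y_val=None, params=None) -> SelectionResult:
    res = SelectionResult(
        method=method,
        retained=selector.retained_,
        importance=selector.importances_,
        params=params or {},
    )
    res.auc_train = auc(y_train, selector.decision_scores(X_train))
    if X_test is not None:
        res.auc_test = auc(y_test, selector.decision_scores(X_test))
    if X_val is not None:
        res.auc_validation = auc(y_val, selector.decision_scores(X_val))
    return res


def select_by_shap(features, labels, seed: int = 0, *, test=None, validation=None,
                   **gbm_params) -> SelectionResult:
    """Fit :class:`ShapSelector` and report retained proteins and AUCs.

    ``test``/``validation`` are optional ``(X, y)`` pairs scored with the
    trained model (the validation cohort is re-scored, not re-selected).
    """
    sel = ShapSelector(seed=seed, **gbm_params).fit(features, labels)
    X_test = y_test = X_val = y_val = None
    if test is not None:
        X_test, y_test = test
    if validation is not None:
        X_val, y_val = validation
    return _evaluate(sel, "gbm_shap", features, labels, X_test, y_test, X_val, y_val,
                     params=sel.get_params())


def select_by_lasso(features, labels, n_folds: int = 10, seed: int = 0, *,
                    test=None, validation=None) -> SelectionResult:
    """Fit :class:`LassoSelector` and report retained proteins and AUCs."""
    sel = LassoSelector(n_folds=n_folds, seed=seed).fit(features, labels)
    X_test = y_test = X_val = y_val = None
    if test is not None:
        X_test, y_test = test
    if validation is not None:
        X_val, y_val = validation
    return _evaluate(sel, "lasso", features, labels, X_test, y_test, X_val, y_val,
                     params=sel.get_params())


def auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the probability that a random case outscores a random control, with
    ties counted 1/2.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
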