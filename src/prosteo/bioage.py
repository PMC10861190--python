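"""Klemera-Doubal proteomic biological age (KDM-Proage) and age acceleration.

The Klemera-Doubal method first regresses every candidate protein on
chronological age (CA), turning each biomarker into an age estimate in years,
then aggregates the per-protein estimates by their information content
``k_j^2 / s_j^2`` (slope squared over residual variance):

    BA_E  = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j k_j^2 / s_j^2
    BA_EC = [ sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2 ]
            / [ sum_j k_j^2 / s_j^2 + 1 / s_BA^2 ]

where ``s_BA`` measures the population spread of true biological age around CA,

    s_BA^2 = Var(BA_E - CA) - (1 - r_char^2)/r_char^2 * (CA_max - CA_min)^2 / (12 m)

with the characteristic correlation ``r_char`` taken as the information-weighted
mean of the absolute protein-age correlations. ``BA_EC`` (the CA-corrected
estimate) is the KDM-Proage; age acceleration is its residual from an OLS
regression on CA.

Candidate proteins are screened by their CA correlation (with BH control) and
pruned for redundancy, keeping the stronger CA-correlate of any highly
correlated pair.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .preprocess import bh_adjust
from .surv import CoxResult, fit_cox

__all__ = ["select_age_proteins", "KlemeraDoubalAge", "fit_kdm", "predict_bioage", "bioage_survival"]

_S_FLOOR = 1e-6  # residual-SD floor keeping weights finite in noise-free tests


def select_age_proteins(
    matrix: pd.DataFrame,
    ca: np.ndarray,
    max_pairwise_r: float = 0.7,
    min_abs_r: float = 0.1,
    q_threshold: float = 0.05,
) -> list[str]:
    """Screen proteins by CA correlation, then greedily remove redundancy.

    Keeps proteins with ``|corr(x_j, CA)| >= min_abs_r`` and BH q below
    ``q_threshold``; among surviving pairs with ``|pairwise r| > max_pairwise_r``
    the weaker CA-correlate is dropped. Deterministic (ties resolved by column
    order).
    """
    ca = np.asarray(ca, dtype=float)
    cors, pvals = [], []
    for c in matrix.columns:
        r, p = stats.pearsonr(matrix[c].to_numpy(), ca)
        cors.append(r)
        pvals.append(p)
    cors = pd.Series(cors, index=matrix.columns)
    qs = pd.Series(bh_adjust(pvals), index=matrix.columns)
    kept = [c for c in matrix.columns if abs(cors[c]) >= min_abs_r and qs[c] < q_threshold]
    if not kept:
        raise ValueError(
            "no protein passes the age-correlation screen; lower min_abs_r or q_threshold"
        )
    # strongest CA-correlates first; drop any candidate too correlated with a keeper
    order = sorted(kept, key=lambda c: (-abs(cors[c]), list(matrix.columns).index(c)))
    final: list[str] = []
    corr = matrix[order].corr()
    for c in order:
        if all(abs(corr.loc[c, k]) <= max_pairwise_r for k in final):
            final.append(c)
    return [c for c in matrix.columns if c in set(final)]


class KlemeraDoubalAge(BaseEstimator):
    """Klemera-Doubal biological-age estimator over a protein panel.

    Fitted attributes: per-protein ``params_`` (q, k, s, r), panel size ``m_``,
    ``s_ba_``, ``r_char_``, CA range, and the OLS coefficients used for the
    acceleration residual.
    """

    def __init__(self, r_char: float | None = None):
        self.r_char = r_char  # override for the characteristic correlation

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, ca: np.ndarray) -> "KlemeraDoubalAge":
        ca = np.asarray(ca, dtype=float)
        if X.shape[1] < 1:
            raise ValueError("need at least one protein")
        if ca.std(ddof=1) == 0:
            raise ValueError("chronological age has zero variance")
        rows = []
        kept = []
        for c in X.columns:
            x = X[c].to_numpy(dtype=float)
            res = stats.linregress(ca, x)
            k, q = float(res.slope), float(res.intercept)
            if abs(k) < 1e-12:
                continue  # uninformative: dropped with the panel shrinking
            resid = x - (q + k * ca)
            s = max(float(resid.std(ddof=1)), _S_FLOOR)
            rows.append((c, q, k, s, float(res.rvalue)))
            kept.append(c)
        if not rows:
            raise ValueError("every protein had a zero age slope")
        self.params_ = pd.DataFrame(
            rows, columns=["protein", "q", "k", "s", "r"]
        ).set_index("protein")
        self.m_ = len(rows)
        self.ca_min_ = float(ca.min())
        self.ca_max_ = float(ca.max())

        info = (self.params_["k"] ** 2 / self.params_["s"] ** 2).to_numpy()
        if self.r_char is not None:
            self.r_char_ = float(self.r_char)
        else:
            self.r_char_ = float(
                np.sum(info * np.abs(self.params_["r"].to_numpy())) / np.sum(info)
            )

        ba_e = self._ba_e(X[kept])
        var_diff = float(np.var(ba_e - ca, ddof=1))
        correction = (
            (1.0 - self.r_char_**2)
            / self.r_char_**2
            * (self.ca_max_ - self.ca_min_) ** 2
            / (12.0 * self.m_)
        )
        s_ba2 = var_diff - correction
        self.s_ba_floored_ = s_ba2 <= 0
        if self.s_ba_floored_:
            s_ba2 = var_diff  # weakly age-correlated panel: keep BA_EC defined
        self.s_ba_ = float(np.sqrt(max(s_ba2, 1e-12)))

        # acceleration residual line fitted on the training set
        ba_ec = self._ba_ec(X[kept], ca)
        slope, intercept = np.polyfit(ca, ba_ec, 1)
        self.accel_slope_ = float(slope)
        self.accel_intercept_ = float(intercept)
        return self

    # ------------------------------------------------------------------
    def _weighted_sums(self, X: pd.DataFrame):
        p = self.params_
        missing = [c for c in p.index if c not in X.columns]
        if missing:
            raise ValueError(f"model protein(s) missing from matrix: {missing}")
        x = X[p.index].to_numpy(dtype=float)
        num = (x - p["q"].to_numpy()) * (p["k"] / p["s"] ** 2).to_numpy()
        den = (p["k"] ** 2 / p["s"] ** 2).to_numpy()
        return num.sum(axis=1), float(den.sum())

    def _ba_e(self, X: pd.DataFrame) -> np.ndarray:
        num, den = self._weighted_sums(X)
        return num / den

    def _ba_ec(self, X: pd.DataFrame, ca: np.ndarray) -> np.ndarray:
        num, den = self._weighted_sums(X)
        w_ca = 1.0 / self.s_ba_**2
        return (num + np.asarray(ca, dtype=float) * w_ca) / (den + w_ca)

    def predict(self, X: pd.DataFrame, ca: np.ndarray) -> pd.DataFrame:
        """Biological ages and acceleration for a scoring set.

        Returns columns ``ca``, ``ba_e`` (uncorrected), ``ba_ec`` (KDM-Proage),
        ``accel`` (OLS residual of ba_ec on ca over the scoring set; sample
        mean 0) and ``accel_std`` (SD units).
        """
        ca = np.asarray(ca, dtype=float)
        ba_e = self._ba_e(X)
        ba_ec = self._ba_ec(X, ca)
        slope, intercept = np.polyfit(ca, ba_ec, 1)
        accel = ba_ec - (intercept + slope * ca)
        sd = accel.std(ddof=1)
        return pd.DataFrame(
            {
                "ca": ca,
                "ba_e": ba_e,
                "ba_ec": ba_ec,
                "accel": accel,
                "accel_std": accel / sd if sd > 0 else np.zeros_like(accel),
            },
            index=X.index,
        )

    def to_json(self, path) -> None:
        payload = {
            "proteins": self.params_.reset_index().to_dict(orient="records"),
            "m": self.m_,
            "s_ba": self.s_ba_,
            "r_char": self.r_char_,
            "ca_range": [self.ca_min_, self.ca_max_],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def fit_kdm(matrix: pd.DataFrame, ca: np.ndarray, **kwargs) -> KlemeraDoubalAge:
    """Fit the Klemera-Doubal model on a (participants x proteins) matrix."""
    return KlemeraDoubalAge(**kwargs).fit(matrix, ca)


def predict_bioage(model: KlemeraDoubalAge, matrix: pd.DataFrame, ca: np.ndarray) -> pd.DataFrame:
    return model.predict(matrix, ca)


def bioage_survival(
    bioages: pd.DataFrame,
    records: pd.DataFrame,
    covariate_tiers: dict[str, list[str]],
    cohort: pd.DataFrame | None = None,
    exposure: str = "ba_ec",
) -> dict[str, CoxResult]:
    """Cox models of osteoporosis on standardized biological age, per tier.

    ``bioages`` is indexed by participant (output of :meth:`predict`);
    ``records`` is a survival table with a ``participant`` column; ``cohort``
    supplies baseline covariates per participant.
    """
    df = records.copy()
    exp_vals = bioages[exposure]
    z = (exp_vals - exp_vals.mean()) / exp_vals.std(ddof=1)
    df["exposure"] = df["participant"].map(z)
    if cohort is not None:
        base = cohort.drop_duplicates("participant").set_index("participant")
        for cols in covariate_tiers.values():
            for c in cols:
                if c not in df.columns:
                    df[c] = df["participant"].map(base[c])
    out = {}
    for tier, cols in covariate_tiers.items():
        out[tier] = fit_cox(df, "exposure", covariates=cols)
    return out
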