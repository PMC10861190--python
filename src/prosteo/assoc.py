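"""Protein-BMD association: random-intercept mixed models and meta-analysis.

Per cohort, a linear mixed-effects model regresses standardized follow-up BMD
on the standardized baseline protein with a per-participant random intercept
(REML). Cohort estimates are pooled by DerSimonian-Laird random-effects
meta-analysis with Cochran's Q and I-squared heterogeneity statistics, and the
protein-level significance flag combines the pooled p-value with a
heterogeneity ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust

__all__ = [
    "AssocEstimate",
    "MetaEstimate",
    "fit_lmm",
    "meta_random_effects",
    "flag_significant",
]


@dataclass
class AssocEstimate:
    protein: str
    beta: float  # BMD-SD per protein-SD
    se: float
    p: float
    n_obs: int
    n_participants: int
    cohort: str = ""
    site: str = ""
    converged: bool = True


@dataclass
class MetaEstimate:
    protein: str
    beta_pooled: float
    se_pooled: float
    p: float
    q_stat: float  # Cochran's Q
    tau2: float
    i2: float  # percent
    k: int
    site: str = ""
    q_bh: float = np.nan  # BH-adjusted p across the protein family
    flagged: bool = False


def fit_lmm(
    protein_z: pd.Series,
    bmd_long: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    protein: str = "",
    cohort: str = "",
    site: str = "",
    outcome_col: str = "bmd_z",
    group_col: str = "participant",
) -> AssocEstimate:
    """Random-intercept LMM of longitudinal BMD on a baseline protein.

    ``bmd_long`` holds one row per participant-visit with the standardized BMD
    outcome and the participant id; ``protein_z`` and ``covariates`` are
    baseline (participant-level) values indexed by participant and broadcast to
    visits. Fitted by REML; returns the protein coefficient with Wald SE and p.
    """
    df = bmd_long[[group_col, outcome_col]].copy()
    df["protein"] = df[group_col].map(protein_z).astype(float)
    exog_cols = ["protein"]
    if covariates is not None:
        for c in covariates.columns:
            df[c] = df[group_col].map(covariates[c]).astype(float)
            exog_cols.append(c)
    df = df.dropna()
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 participants")

    exog = df[exog_cols].to_numpy()
    # drop collinear covariate columns up front so MixedLM sees a full-rank design
    design = np.column_stack([np.ones(len(df)), exog])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep, dropped = [np.ones(len(df))], []
        for j, name in enumerate(exog_cols):
            cand = np.column_stack(keep + [exog[:, j]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                keep.append(exog[:, j])
            else:
                dropped.append(name)
        raise ValueError(f"singular design: collinear column(s) {dropped}")

    import statsmodels.api as sm

    X = sm.add_constant(exog)
    single_visit = df[group_col].value_counts().max() == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_visit:
            # the random intercept is unidentified with one observation per
            # participant; the model reduces exactly to OLS
            fit = sm.OLS(df[outcome_col].to_numpy(), X).fit()
        else:
            model = sm.MixedLM(df[outcome_col].to_numpy(), X, groups=df[group_col].to_numpy())
            try:
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            except Exception as exc:  # pragma: no cover - optimizer failure path
                raise RuntimeError(f"mixed-model fit failed: {exc}") from exc
    # protein is the first slope after the intercept
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se <= 0:
        # degenerate (near noise-free) fit: REML variance components collapse
        # and the Wald SE is undefined; fall back to the OLS SE, floored
        resid = df[outcome_col].to_numpy() - X @ np.asarray(fit.params[: X.shape[1]])
        dof = max(len(df) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 1e-24)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return AssocEstimate(
        protein=protein,
        beta=beta,
        se=se,
        p=p,
        n_obs=len(df),
        n_participants=int(df[group_col].nunique()),
        cohort=cohort,
        site=site,
        converged=bool(getattr(fit, "converged", True)),
    )


def meta_random_effects(estimates: list[AssocEstimate]) -> MetaEstimate:
    """DerSimonian-Laird random-effects pooling of per-cohort estimates.

    With fixed-effect weights ``w_i = 1/se_i^2``:

    - ``Q = sum w_i (b_i - b_fixed)^2`` with df = k - 1,
    - ``tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i))``,
    - random-effects weights ``w*_i = 1/(se_i^2 + tau^2)`` give the pooled
      estimate and ``se_pooled = (sum w*_i)^(-1/2)``,
    - ``I^2 = max(0, (Q - (k-1)) / Q) * 100``.
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("meta-analysis needs at least 2 estimates")
    b = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    b_fixed = float(np.sum(w * b) / np.sum(w))
    q_stat = float(np.sum(w * (b - b_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q_stat - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    beta_pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    p = float(2.0 * stats.norm.sf(abs(beta_pooled) / se_pooled))
    i2 = max(0.0, (q_stat - (k - 1)) / q_stat) * 100.0 if q_stat > 0 else 0.0
    return MetaEstimate(
        protein=estimates[0].protein,
        beta_pooled=beta_pooled,
        se_pooled=se_pooled,
        p=p,
        q_stat=q_stat,
        tau2=tau2,
        i2=i2,
        k=k,
        site=estimates[0].site,
    )


def flag_significant(
    meta: list[MetaEstimate], p_threshold: float = 0.05, i2_threshold: float = 30.0
) -> list[MetaEstimate]:
    """Flag pooled estimates with p < 0.05 and I-squared < 30 percent.

    BH-adjusted q-values are attached per site family for reporting; the flag
    itself uses the raw pooled p (strict inequalities on both criteria).
    Returns the flagged subset; the q/flag fields are set in place on all
    inputs.
    """
    if not meta:
        return []
    df = pd.DataFrame({"site": [m.site for m in meta], "p": [m.p for m in meta]})
    for site, grp in df.groupby("site"):
        qs = bh_adjust(grp["p"].to_numpy())
        for idx, qv in zip(grp.index, qs):
            meta[idx].q_bh = float(qv)
    flagged = []
    for m in meta:
        m.flagged = bool(m.p < p_threshold and m.i2 < i2_threshold)
        if m.flagged:
            flagged.append(m)
    return flagged
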