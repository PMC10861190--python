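"""Time-to-osteoporosis survival analysis.

Survival records are built from per-visit T-score statuses (event time = first
visit with osteoporosis, censoring at the last attended visit; prevalent
baseline cases excluded). Cox proportional-hazards models use the Efron
approximation for the heavy visit-level ties; dose-response uses a restricted
(natural) cubic spline basis with Harrell's default knot quantiles; quartile
models report hazard ratios against the lowest quartile and an ordinal trend
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "SurvivalRecord",
    "CoxResult",
    "make_survival_records",
    "fit_cox",
    "rcs_expand",
    "rcs_knots",
    "quartile_hr",
]


@dataclass
class CoxResult:
    beta: float  # log-hazard per exposure unit
    hr: float
    ci: tuple
    p: float
    n_events: int
    n: int
    ties: str = "efron"
    extras: dict = field(default_factory=dict)


def make_survival_records(
    statuses: pd.DataFrame,
    *,
    participant_col: str = "participant",
    time_col: str = "time_years",
    status_col: str = "status",
) -> tuple[pd.DataFrame, dict]:
    """Build one survival record per participant from visit-level statuses.

    Event time is years from the first BMD visit to the first visit classified
    osteoporotic; participants without an event are censored at their last
    attended visit. Participants osteoporotic at their first visit are excluded
    as prevalent cases; the returned log dictionary counts exclusions.
    """
    records = []
    n_prevalent = 0
    n_no_visits = 0
    for pid, grp in statuses.groupby(participant_col, sort=True):
        grp = grp.sort_values(time_col)
        if len(grp) == 0:  # pragma: no cover - defensive
            n_no_visits += 1
            continue
        t0 = grp[time_col].iloc[0]
        op = grp[status_col].to_numpy() == "osteoporosis"
        if op[0]:
            n_prevalent += 1
            continue
        if op.any():
            t_event = grp[time_col].to_numpy()[op.argmax()] - t0
            records.append((pid, float(t_event), True))
        else:
            records.append((pid, float(grp[time_col].iloc[-1] - t0), False))
    out = pd.DataFrame(records, columns=["participant", "time", "event"])
    out = out[out["time"] > 0].reset_index(drop=True)
    log = {"n_prevalent_excluded": n_prevalent, "n_no_visits": n_no_visits,
           "n_records": len(out), "n_events": int(out["event"].sum())}
    return out, log


def fit_cox(
    records: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    *,
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards coefficient for one exposure with Wald CI."""
    covariates = covariates or []
    cols = [time_col, event_col, exposure] + covariates
    df = records[cols].dropna().copy()
    if df[event_col].sum() < 1:
        raise ValueError("no events")
    if df[exposure].nunique() < 2:
        raise ValueError("exposure does not vary")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col=time_col, event_col=event_col)
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed (separation?): {exc}") from exc
    beta = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    z = 1.959963984540054
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    return CoxResult(
        beta=beta,
        hr=float(np.exp(beta)),
        ci=ci,
        p=float(cph.summary.loc[exposure, "p"]),
        n_events=int(df[event_col].sum()),
        n=len(df),
        ties=ties,
        extras={"se": se},
    )


def rcs_knots(x, n_knots: int = 4) -> np.ndarray:
    """Harrell's default knot placement quantiles.

    3 knots: 0.10/0.50/0.90; 4 knots: 0.05/0.35/0.65/0.95;
    5 knots: 0.05/0.275/0.50/0.725/0.95.
    """
    quantiles = {
        3: (0.10, 0.50, 0.90),
        4: (0.05, 0.35, 0.65, 0.95),
        5: (0.05, 0.275, 0.50, 0.725, 0.95),
    }
    if n_knots not in quantiles:
        raise ValueError("n_knots must be 3, 4 or 5")
    knots = np.quantile(np.asarray(x, dtype=float), quantiles[n_knots])
    if len(np.unique(knots)) != n_knots:
        raise ValueError("duplicate knots; too few distinct exposure values")
    return knots


def rcs_expand(x, n_knots: int = 4, knots: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Restricted cubic spline basis (natural spline, Harrell normalization).

    Returns ``(basis, knots)`` where the basis has ``n_knots - 1`` columns: the
    linear term followed by the restricted cubic terms

    ``C_j(x) = [(x - t_j)+^3 - (x - t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
    + (x - t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1})] / (t_k - t_1)^2``

    which are linear beyond the boundary knots with continuous first and
    second derivatives everywhere.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = rcs_knots(x, n_knots)
    else:
        knots = np.sort(np.asarray(knots, dtype=float))
        if len(np.unique(knots)) != len(knots):
            raise ValueError("duplicate knots")
    k = len(knots)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def plus3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        cj = (
            plus3(x - tj)
            - plus3(x - tk1) * (tk - tj) / (tk - tk1)
            + plus3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(cj)
    return np.column_stack(cols), knots


def rcs_dose_response(
    records: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    n_knots: int = 4,
    grid: np.ndarray | None = None,
    reference: float | None = None,
) -> pd.DataFrame:
    """Cox dose-response curve on a restricted cubic spline of the exposure.

    Returns a table of (exposure grid, log-HR relative to the reference value,
     95% CI) suitable for plotting.
    """
    covariates = covariates or []
    x = records[exposure].to_numpy(dtype=float)
    basis, knots = rcs_expand(x, n_knots)
    spline_cols = [f"_rcs{j}" for j in range(basis.shape[1])]
    df = records[["time", "event"] + covariates].copy()
    for j, c in enumerate(spline_cols):
        df[c] = basis[:, j]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df.dropna(), duration_col="time", event_col="event")
    params = cph.params_[spline_cols].to_numpy()
    cov = cph.variance_matrix_.loc[spline_cols, spline_cols].to_numpy()
    if grid is None:
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 50)
    if reference is None:
        reference = float(np.median(x))
    gb, _ = rcs_expand(grid, knots=knots)
    rb, _ = rcs_expand(np.array([reference]), knots=knots)
    delta = gb - rb
    log_hr = delta @ params
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, cov, delta))
    z = 1.959963984540054
    return pd.DataFrame(
        {"exposure": grid, "log_hr": log_hr, "lo": log_hr - z * se, "hi": log_hr + z * se}
    )


def quartile_hr(
    records: pd.DataFrame,
    quartiles,
    covariates: list[str] | None = None,
) -> dict:
    """Hazard ratios of quartiles Q2-Q4 versus Q1 plus an ordinal trend test.

    The trend p-value is the Wald p for the quartile rank (1-4) entered as a
    single continuous covariate.
    """
    covariates = covariates or []
    q = np.asarray(quartiles)
    df = records[["time", "event"] + covariates].copy()
    levels = np.unique(q)
    if len(levels) < 2:
        raise ValueError("quartile exposure does not vary")
    events_per = {lvl: int(records.loc[q == lvl, "event"].sum()) for lvl in levels}
    if sum(v > 0 for v in events_per.values()) < 2:
        raise ValueError("events present in fewer than 2 quartiles")
    for lvl in levels[1:]:
        df[f"q{lvl}"] = (q == lvl).astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    z = 1.959963984540054
    out = {"hr": {}, "events_per_quartile": events_per}
    for lvl in levels[1:]:
        name = f"q{lvl}"
        beta = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        out["hr"][int(lvl)] = {
            "hr": float(np.exp(beta)),
            "ci": (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
            "p": float(cph.summary.loc[name, "p"]),
        }
    trend = records[["time", "event"] + covariates].copy()
    trend["qrank"] = q.astype(float)
    cph_t = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph_t.fit(trend, duration_col="time", event_col="event")
    out["p_trend"] = float(cph_t.summary.loc["qrank", "p"])
    return out
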