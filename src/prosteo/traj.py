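"""Latent-class linear trajectory model for longitudinal BMD.

A finite mixture of linear growth curves ``y_it = a_k + b_k t_it + eps``,
``eps ~ N(0, sigma^2)`` with a shared residual SD, fitted by EM with multiple
restarts. Model order is chosen over K = 1..5 by BIC subject to an average
posterior probability of assignment (APPA) floor. One-way ANOVA compares
baseline protein means across the assigned classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = ["TrajectoryModel", "fit_lctm", "select_classes", "anova_across_classes"]

_LOG2PI = float(np.log(2.0 * np.pi))


class TrajectoryModel(BaseEstimator):
    """EM-fitted mixture of linear growth curves with K latent classes.

    Parameters
    ----------
    n_classes : number of latent classes K.
    n_restarts : random restarts; the first is initialized from k-means on
        per-person OLS (intercept, slope), the rest from perturbed
        responsibilities. The best log-likelihood is kept.
    tol : EM convergence threshold on the change in log-likelihood.
    """

    def __init__(
        self,
        n_classes: int = 3,
        n_restarts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int = 0,
    ):
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, y: np.ndarray, times: np.ndarray) -> "TrajectoryModel":
        """Fit on an (n_participants, n_visits) outcome array.

        ``times`` is either a length-n_visits vector shared by everyone or an
        array matching ``y``. Missing visits are NaN in ``y``.
        """
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ValueError("y must be 2-D (participants x visits)")
        times = np.asarray(times, dtype=float)
        if times.ndim == 1:
            times = np.broadcast_to(times, y.shape)
        mask = np.isfinite(y)
        n_visits_per = mask.sum(axis=1)
        if (n_visits_per >= 2).sum() < self.n_classes:
            raise ValueError("need at least K participants with >= 2 visits")
        K = self.n_classes

        best = None
        rng = np.random.default_rng(self.seed)
        init_resp = self._kmeans_init(y, times, mask, K, rng)
        for restart in range(self.n_restarts):
            if restart == 0:
                resp = init_resp
            else:
                resp = rng.dirichlet(np.ones(K), size=y.shape[0])
            try:
                params, ll, history = self._em(y, times, mask, resp)
            except np.linalg.LinAlgError:
                continue
            if best is None or ll > best[1]:
                best = (params, ll, history)
        if best is None:
            raise RuntimeError("EM failed to converge in all restarts")
        (a, b, pi, sigma), ll, history = best

        # canonical labelling: classes ordered by intercept ascending
        order = np.argsort(a, kind="stable")
        a, b, pi = a[order], b[order], pi[order]
        resp = self._responsibilities(y, times, mask, a, b, pi, sigma)

        self.intercepts_ = a
        self.slopes_ = b
        self.weights_ = pi
        self.sigma_ = sigma
        self.log_likelihood_ = ll
        self.ll_history_ = history
        self.responsibilities_ = resp
        self.labels_ = resp.argmax(axis=1)
        n = y.shape[0]
        self.n_params_ = 2 * K + (K - 1) + 1
        self.bic_ = -2.0 * ll + self.n_params_ * np.log(n)
        appa = np.full(K, np.nan)
        for k in range(K):
            members = self.labels_ == k
            if members.any():
                appa[k] = resp[members, k].mean()
        self.appa_ = appa
        self.degenerate_classes_ = list(np.where(pi < 1e-6)[0])
        return self

    def predict(self, y: np.ndarray, times: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        times = np.asarray(times, dtype=float)
        if times.ndim == 1:
            times = np.broadcast_to(times, y.shape)
        resp = self._responsibilities(
            y, times, np.isfinite(y), self.intercepts_, self.slopes_, self.weights_, self.sigma_
        )
        return resp.argmax(axis=1)

    # ------------------------------------------------------------------
    @staticmethod
    def _kmeans_init(y, times, mask, K, rng):
        """Responsibilities from k-means on per-person OLS (intercept, slope)."""
        n = y.shape[0]
        feats = np.zeros((n, 2))
        for i in range(n):
            m = mask[i]
            ti, yi = times[i, m], y[i, m]
            if m.sum() >= 2 and np.ptp(ti) > 0:
                slope, intercept = np.polyfit(ti, yi, 1)
            else:
                intercept, slope = (yi.mean() if m.any() else 0.0), 0.0
            feats[i] = (intercept, slope)
        feats = (feats - feats.mean(0)) / np.where(feats.std(0) > 0, feats.std(0), 1.0)
        km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(feats)
        resp = np.full((n, K), 0.05 / max(K - 1, 1))
        resp[np.arange(n), labels] = 0.95
        if K == 1:
            resp[:] = 1.0
        return resp / resp.sum(axis=1, keepdims=True)

    @staticmethod
    def _class_loglik(y, times, mask, a, b, sigma):
        """(n, K) per-participant log-likelihood under each class."""
        K = a.size
        resid = y[:, :, None] - (a[None, None, :] + b[None, None, :] * times[:, :, None])
        ll = -0.5 * (resid / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI
        ll = np.where(mask[:, :, None], ll, 0.0)
        return ll.sum(axis=1).reshape(y.shape[0], K)

    @classmethod
    def _responsibilities(cls, y, times, mask, a, b, pi, sigma):
        logr = cls._class_loglik(y, times, mask, a, b, sigma) + np.log(pi)[None, :]
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        return r / r.sum(axis=1, keepdims=True)

    def _em(self, y, times, mask, resp):
        K = resp.shape[1]
        a = np.zeros(K)
        b = np.zeros(K)
        sigma = 1.0
        pi = resp.mean(axis=0)
        ll_prev = -np.inf
        history = []
        for _ in range(self.max_iter):
            # M-step: weighted least squares per class over all observations
            sse = 0.0
            n_obs = 0.0
            for k in range(K):
                w = np.where(mask, resp[:, k][:, None], 0.0)
                sw = w.sum()
                if sw < 1e-12:
                    continue
                t_bar = (w * times).sum() / sw
                y_bar = (w * np.nan_to_num(y)).sum() / sw
                stt = (w * (times - t_bar) ** 2).sum()
                sty = (w * (times - t_bar) * (np.nan_to_num(y) - y_bar)).sum()
                b[k] = sty / stt if stt > 0 else 0.0
                a[k] = y_bar - b[k] * t_bar
                resid = np.nan_to_num(y) - (a[k] + b[k] * times)
                sse += (w * resid**2).sum()
                n_obs += sw
            sigma = max(np.sqrt(sse / n_obs), 1e-8)
            pi = np.clip(resp.mean(axis=0), 1e-12, None)
            pi = pi / pi.sum()

            # E-step + observed-data log-likelihood
            cl = self._class_loglik(y, times, mask, a, b, sigma) + np.log(pi)[None, :]
            m = cl.max(axis=1, keepdims=True)
            ll = float((m.ravel() + np.log(np.exp(cl - m).sum(axis=1))).sum())
            history.append(ll)
            resp = np.exp(cl - m)
            resp = resp / resp.sum(axis=1, keepdims=True)
            if ll - ll_prev < self.tol and np.isfinite(ll_prev):
                break
            ll_prev = ll
        return (a.copy(), b.copy(), pi.copy(), sigma), ll, history


def fit_lctm(
    bmd_long: pd.DataFrame,
    n_classes: int,
    seed: int = 0,
    *,
    value_col: str = "bmd_z",
    time_col: str = "time_years",
    participant_col: str = "participant",
    **kwargs,
) -> TrajectoryModel:
    """Fit a K-class trajectory model on a long-format BMD table."""
    wide = bmd_long.pivot_table(index=participant_col, columns=time_col, values=value_col)
    times = wide.columns.to_numpy(dtype=float)
    model = TrajectoryModel(n_classes=n_classes, seed=seed, **kwargs)
    model.fit(wide.to_numpy(), times)
    model.participants_ = wide.index.to_numpy()
    return model


def select_classes(
    fits: list[TrajectoryModel], appa_threshold: float = 0.7
) -> TrajectoryModel:
    """Choose the model with the lowest BIC among fits meeting the APPA floor.

    A fit qualifies when every class APPA is at least ``appa_threshold``; if
    none qualifies, the lowest-BIC fit overall is returned with
    ``appa_warning_`` set. Equal BICs break toward fewer classes.
    """
    if not fits:
        raise ValueError("no fits supplied")
    ordered = sorted(fits, key=lambda f: (f.bic_, f.n_classes))
    qualifying = [f for f in ordered if np.nanmin(f.appa_) >= appa_threshold]
    if qualifying:
        best = qualifying[0]
        best.appa_warning_ = False
    else:
        best = ordered[0]
        best.appa_warning_ = True
    return best


def anova_across_classes(protein_z: np.ndarray, assignment: np.ndarray):
    """One-way fixed-effects ANOVA of a baseline protein across classes.

    Returns ``(F, df_between, df_within, p)``.
    """
    x = np.asarray(protein_z, dtype=float)
    g = np.asarray(assignment)
    groups = [x[g == lvl] for lvl in np.unique(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 classes")
    if any(len(grp) < 2 for grp in groups):
        raise ValueError("every class needs at least 2 members")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = x.size - len(groups)
    return float(f), int(df1), int(df2), float(p)
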