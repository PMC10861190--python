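"""Survival records, Cox partial likelihood, restricted cubic splines."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from prosteo import surv


def _status_frame(rows):
    return pd.DataFrame(rows, columns=["participant", "time_years", "status"])


class TestMakeSurvivalRecords:
    def test_event_at_third_visit(self):
        df = _status_frame([("a", 0.0, "normal"), ("a", 3.3, "osteopenia"),
                            ("a", 6.6, "osteoporosis")])
        rec, log = surv.make_survival_records(df)
        assert rec.loc[0, "event"] and rec.loc[0, "time"] == pytest.approx(6.6)

    def test_censored_at_last_visit(self):
        df = _status_frame([("a", 0.0, "normal"), ("a", 3.3, "normal"),
                            ("a", 6.6, "normal")])
        rec, _ = surv.make_survival_records(df)
        assert not rec.loc[0, "event"] and rec.loc[0, "time"] == pytest.approx(6.6)

    def test_prevalent_case_excluded(self):
        df = _status_frame([("a", 0.0, "osteoporosis"), ("a", 3.3, "osteoporosis"),
                            ("b", 0.0, "normal"), ("b", 3.3, "normal")])
        rec, log = surv.make_survival_records(df)
        assert list(rec["participant"]) == ["b"]
        assert log["n_prevalent_excluded"] == 1


class TestFitCox:
    def test_four_subject_partial_likelihood_oracle(self):
        """beta maximizes PL = [e^b/(2e^b+2)] [1/(e^b+2)] [e^b/(e^b+1)]
        for exposures (1,0,1,0) and ordered event times (1,2,3,4)."""
        rec = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [True, True, True, True],
            "z": [1.0, 0.0, 1.0, 0.0],
        })
        res = surv.fit_cox(rec, "z")

        def neg_log_pl(b):
            eb = np.exp(b)
            return -(np.log(eb / (2 * eb + 2)) + np.log(1 / (eb + 2))
                     + np.log(eb / (eb + 1)))

        opt = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert res.beta == pytest.approx(opt.x, abs=1e-4)

    def test_partial_likelihood_is_local_maximum(self, rng):
        n = 200
        z = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * z))
        c = rng.exponential(2.0, n)
        rec = pd.DataFrame({"time": np.minimum(t, c), "event": t <= c, "z": z})
        res = surv.fit_cox(rec, "z")

        def log_pl(beta):
            order = np.argsort(rec["time"].to_numpy())
            tt = rec["time"].to_numpy()[order]
            ee = rec["event"].to_numpy()[order]
            zz = rec["z"].to_numpy()[order]
            ll = 0.0
            for i in range(n):
                if ee[i]:
                    risk = zz[tt >= tt[i]]
                    ll += beta * zz[i] - np.log(np.sum(np.exp(beta * risk)))
            return ll

        best = log_pl(res.beta)
        probes = rng.uniform(res.beta - 2, res.beta + 2, 200)
        assert all(log_pl(b) <= best + 1e-8 for b in probes)

    def test_efron_equals_breslow_without_ties(self, rng):
        """On tie-free data the Efron fit equals an independently coded
        Breslow-Newton solver."""
        n = 60
        z = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * z))
        rec = pd.DataFrame({"time": t, "event": np.ones(n, bool), "z": z})
        res = surv.fit_cox(rec, "z")

        order = np.argsort(t)
        zz, tt = z[order], t[order]
        beta = 0.0
        for _ in range(50):
            grad, hess = 0.0, 0.0
            for i in range(n):
                risk = zz[i:]
                w = np.exp(beta * risk)
                m1 = np.sum(w * risk) / np.sum(w)
                m2 = np.sum(w * risk**2) / np.sum(w)
                grad += zz[i] - m1
                hess += m2 - m1**2
            step = grad / hess
            beta += step
            if abs(step) < 1e-12:
                break
        assert res.beta == pytest.approx(beta, abs=1e-6)

    def test_permutation_null_coverage(self, rng):
        n = 300
        z = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        hits = 0
        for _ in range(100):
            rec = pd.DataFrame({"time": t, "event": np.ones(n, bool),
                                "z": rng.permutation(z)})
            res = surv.fit_cox(rec, "z")
            if res.ci[0] <= 1.0 <= res.ci[1]:
                hits += 1
        assert hits >= 88

    def test_no_events_rejected(self, rng):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False],
                            "z": [0.0, 1.0]})
        with pytest.raises(ValueError):
            surv.fit_cox(rec, "z")


class TestRcs:
    def test_linear_below_first_knot(self, rng):
        x = rng.uniform(0, 10, 500)
        basis, knots = surv.rcs_expand(x, n_knots=4)
        below = x < knots[0]
        assert below.any()
        np.testing.assert_allclose(basis[below, 1:], 0.0, atol=1e-12)

    def test_second_derivative_continuous_at_knots(self):
        x_fit = np.linspace(0, 10, 200)
        _, knots = surv.rcs_expand(x_fit, n_knots=4)
        h = 1e-4
        for t in knots:
            for side in (-1, 1):
                pts = np.array([t - h, t, t + h])
                b, _ = surv.rcs_expand(pts, knots=knots)
                second = (b[0] - 2 * b[1] + b[2]) / h**2
                pts2 = pts + side * h
                b2, _ = surv.rcs_expand(pts2, knots=knots)
                second2 = (b2[0] - 2 * b2[1] + b2[2]) / h**2
                np.testing.assert_allclose(second, second2, atol=1e-2)

    def test_matches_textbook_formula_oracle(self, rng):
        """Basis values at probe points match a directly coded natural-spline
        truncated-power formula."""
        knots = np.array([1.0, 3.0, 6.0, 9.0])
        probes = rng.uniform(0, 10, 10)
        basis, _ = surv.rcs_expand(probes, knots=knots)
        t1, t2, t3, t4 = knots

        def trunc3(v):
            return np.maximum(v, 0.0) ** 3

        for j, tj in enumerate([t1, t2]):
            expected = (
                trunc3(probes - tj)
                - trunc3(probes - t3) * (t4 - tj) / (t4 - t3)
                + trunc3(probes - t4) * (t3 - tj) / (t4 - t3)
            ) / (t4 - t1) ** 2
            np.testing.assert_allclose(basis[:, 1 + j], expected, atol=1e-10)

    def test_reproduces_linear_function_exactly(self, rng):
        x = rng.uniform(0, 10, 300)
        y = 2.0 + 0.5 * x
        basis, _ = surv.rcs_expand(x, n_knots=4)
        X = np.column_stack([np.ones_like(x), basis])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        assert np.abs(resid).max() < 1e-8
        np.testing.assert_allclose(coef[2:], 0.0, atol=1e-8)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            surv.rcs_expand(np.ones(10), n_knots=4)
        with pytest.raises(ValueError):
            surv.rcs_expand(np.linspace(0, 1, 10), knots=[0.2, 0.2, 0.5, 0.8])


class TestQuartileHr:
    def _records(self, rng, n=400, effect=0.0):
        z = rng.normal(size=n)
        t = rng.exponential(np.exp(-effect * z))
        c = np.full(n, 2.0)
        return pd.DataFrame({"time": np.minimum(t, c), "event": t <= c, "z": z})

    def test_null_covers_one(self, rng):
        """Exposure-free hazard: quartile HR CIs cover 1 at ~95% rate."""
        from prosteo.score import prs_quartiles

        covered = total = 0
        for _ in range(20):
            rec = self._records(rng, effect=0.0)
            q, _ = prs_quartiles(rec["z"].to_numpy())
            out = surv.quartile_hr(rec, q)
            for res in out["hr"].values():
                covered += res["ci"][0] <= 1.0 <= res["ci"][1]
                total += 1
        assert covered / total >= 0.85

    def test_monotone_risk_q4_exceeds_q2(self, rng):
        from prosteo.score import prs_quartiles

        wins = 0
        for _ in range(10):
            rec = self._records(rng, effect=0.8)
            q, _ = prs_quartiles(rec["z"].to_numpy())
            out = surv.quartile_hr(rec, q)
            if out["hr"][4]["hr"] > out["hr"][2]["hr"]:
                wins += 1
        assert wins >= 9
        assert out["p_trend"] < 0.05

    def test_constant_exposure_rejected(self, rng):
        rec = self._records(rng)
        with pytest.raises(ValueError):
            surv.quartile_hr(rec, np.ones(len(rec), dtype=int))
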