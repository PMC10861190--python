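"""Two-sample Mendelian randomization on harmonized GWAS summary statistics.

Instruments pass a genome-wide significance filter (p <= 5e-8) and allele
harmonization (outcome effects aligned to the exposure effect allele;
strand-ambiguous palindromic SNPs with intermediate allele frequency dropped).
Estimators: per-SNP Wald ratio, inverse-variance weighted (IVW) regression
through the origin, MR-Egger (slope + directional-pleiotropy intercept),
weighted median, and kernel-mode estimators (simple and weighted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrEstimate",
    "filter_instruments",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimators",
    "run_all_estimators",
]

GWAS_P_THRESHOLD = 5e-8
_PALINDROMIC = {frozenset("AT"), frozenset("CG")}
_EAF_AMBIGUOUS = (0.42, 0.58)


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    extras: dict | None = None


def filter_instruments(rows: pd.DataFrame, p_col: str = "p_x",
                       threshold: float = GWAS_P_THRESHOLD) -> pd.DataFrame:
    """Keep genome-wide significant instruments (p <= threshold, inclusive)."""
    kept = rows[rows[p_col] <= threshold].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError(f"no instrument passes p <= {threshold:g}")
    return kept


def _complement(allele: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[allele]


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Outcome effects are sign-flipped when the outcome effect allele matches the
    exposure's other allele (directly or on the complementary strand).
    Palindromic SNPs (A/T or C/G) with effect-allele frequency in (0.42, 0.58)
    or unknown are dropped as strand-ambiguous, as are allele-incompatible
    SNPs. Idempotent: harmonizing an already harmonized set changes nothing.
    """
    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    shared = exp.index.intersection(out.index)
    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        pair = frozenset((ea_e, oa_e))
        if pair in _PALINDROMIC:
            eaf = e.get("eaf", np.nan)
            if not np.isfinite(eaf) or _EAF_AMBIGUOUS[0] < eaf < _EAF_AMBIGUOUS[1]:
                continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            flip = False
        elif (ea_o, oa_o) == (oa_e, ea_e):
            flip = True
        elif (ea_o, oa_o) == (_complement(ea_e), _complement(oa_e)):
            flip = False
        elif (ea_o, oa_o) == (_complement(oa_e), _complement(ea_e)):
            flip = True
        else:
            continue  # allele-incompatible
        b_y = -float(o["beta"]) if flip else float(o["beta"])
        rows.append(
            {
                "snp": snp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "b_x": float(e["beta"]),
                "se_x": float(e["se"]),
                "p_x": float(e.get("pval", np.nan)),
                "b_y": b_y,
                "se_y": float(o["se"]),
                "eaf": float(e.get("eaf", np.nan)),
            }
        )
    if not rows:
        raise ValueError("no SNP survived harmonization")
    return pd.DataFrame(rows)


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0


def wald_ratio(b_x: float, se_x: float, b_y: float, se_y: float) -> MrEstimate:
    """Single-instrument ratio estimate; first-order SE = se_y / |b_x|."""
    if b_x == 0:
        raise ValueError("b_x must be nonzero")
    beta = b_y / b_x
    se = se_y / abs(b_x)
    return MrEstimate("wald", float(beta), float(se), _normal_p(beta, se), 1)


def _ratios(instruments: pd.DataFrame):
    b_x = instruments["b_x"].to_numpy(dtype=float)
    b_y = instruments["b_y"].to_numpy(dtype=float)
    se_y = instruments["se_y"].to_numpy(dtype=float)
    if np.any(b_x == 0):
        raise ValueError("b_x must be nonzero for ratio-based estimators")
    ratio = b_y / b_x
    se_ratio = se_y / np.abs(b_x)
    return ratio, se_ratio


def ivw(instruments: pd.DataFrame) -> MrEstimate:
    """Inverse-variance weighted estimate: WLS of b_Y on b_X through the origin.

    Fixed-effect SE by default; when the residual overdispersion Q/(k-1)
    exceeds 1, the SE is inflated multiplicatively (random-effects IVW) and the
    flag is recorded in ``extras``.
    """
    k = len(instruments)
    if k < 2:
        raise ValueError("IVW needs >= 2 SNPs (use wald_ratio)")
    b_x = instruments["b_x"].to_numpy(dtype=float)
    b_y = instruments["b_y"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_y"].to_numpy(dtype=float) ** 2
    beta = float(np.sum(w * b_x * b_y) / np.sum(w * b_x**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w * b_x**2)))
    q = float(np.sum(w * (b_y - beta * b_x) ** 2))
    overdispersion = q / (k - 1)
    inflated = overdispersion > 1.0
    se = se_fixed * np.sqrt(overdispersion) if inflated else se_fixed
    return MrEstimate(
        "ivw", beta, float(se), _normal_p(beta, se), k,
        extras={"q": q, "overdispersion": overdispersion, "random_effects": inflated},
    )


def mr_egger(instruments: pd.DataFrame) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger: WLS of b_Y on b_X with intercept, weights 1/se_Y^2.

    Returns (slope, intercept) estimates; the intercept tests directional
    pleiotropy. SEs carry a multiplicative overdispersion factor floored at 1,
    with t-distribution p-values on k - 2 df.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    # orient so all exposure effects are positive (standard Egger convention)
    sign = np.sign(instruments["b_x"].to_numpy(dtype=float))
    if np.any(sign == 0):
        raise ValueError("b_x must be nonzero")
    b_x = instruments["b_x"].to_numpy(dtype=float) * sign
    b_y = instruments["b_y"].to_numpy(dtype=float) * sign
    if np.ptp(b_x) == 0:
        raise ValueError("no spread in b_x (no leverage for the intercept)")
    w = 1.0 / instruments["se_y"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones(k), b_x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * b_y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = b_y - X @ coef
    phi = max(float(np.sum(w * resid**2) / (k - 2)), 1.0)
    cov = np.linalg.inv(xtwx) * phi
    ses = np.sqrt(np.diag(cov))
    df = k - 2

    def t_p(b, s):
        return float(2.0 * stats.t.sf(abs(b) / s, df)) if s > 0 else 0.0

    slope = MrEstimate("egger_slope", float(coef[1]), float(ses[1]), t_p(coef[1], ses[1]), k)
    intercept = MrEstimate(
        "egger_intercept", float(coef[0]), float(ses[0]), t_p(coef[0], ses[0]), k
    )
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation between bracketing values."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    Weights are the inverse variances of the ratios; consistent when valid
    instruments carry more than half the weight. SE by seeded parametric
    bootstrap of (b_X, b_Y).
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("weighted median needs >= 3 SNPs")
    ratio, se_ratio = _ratios(instruments)
    w = 1.0 / se_ratio**2
    beta = _weighted_median(ratio, w)

    rng = np.random.default_rng(seed)
    b_x = instruments["b_x"].to_numpy(dtype=float)
    se_x = instruments["se_x"].to_numpy(dtype=float)
    b_y = instruments["b_y"].to_numpy(dtype=float)
    se_y = instruments["se_y"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = b_x + rng.normal(0.0, 1.0, k) * se_x
        by = b_y + rng.normal(0.0, 1.0, k) * se_y
        bx = np.where(bx == 0, 1e-12, bx)
        r = by / bx
        boots[i] = _weighted_median(r, np.abs(bx) ** 2 / se_y**2)
    se = float(boots.std(ddof=1))
    return MrEstimate("weighted_median", beta, se, _normal_p(beta, se), k)


def _mode_point(ratio: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    """Argmax of the weighted Gaussian-kernel density of the ratios."""
    grid = np.linspace(ratio.min() - 3 * bandwidth, ratio.max() + 3 * bandwidth, 2000)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / bandwidth) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def _msad_bandwidth(ratio: np.ndarray, se_ratio: np.ndarray, factor: float) -> float:
    """Modified Silverman bandwidth on the ratio scale."""
    k = ratio.size
    w = 1.0 / se_ratio**2
    mu = np.sum(w * ratio) / np.sum(w)
    s = np.sqrt(np.sum(w * (ratio - mu) ** 2) / np.sum(w))
    mad = stats.median_abs_deviation(ratio, scale="normal")
    disp = min(s, mad) if mad > 0 else s
    h = factor * 0.9 * disp / k**0.2
    return max(h, 1e-8)


def mode_estimators(
    instruments: pd.DataFrame,
    mode: str = "simple",
    bandwidth_factor: float = 1.0,
    seed: int = 0,
    n_boot: int = 1000,
) -> MrEstimate:
    """Mode-based estimate: argmax of the kernel-smoothed ratio density.

    ``mode="simple"`` weights all ratios equally; ``mode="weighted"`` weights
    by the inverse ratio variance. SE by seeded parametric bootstrap.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("mode estimators need >= 3 SNPs")
    if mode not in ("simple", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    ratio, se_ratio = _ratios(instruments)
    h = _msad_bandwidth(ratio, se_ratio, bandwidth_factor)
    weights = np.ones(k) if mode == "simple" else 1.0 / se_ratio**2
    beta = _mode_point(ratio, weights, h)

    rng = np.random.default_rng(seed)
    b_x = instruments["b_x"].to_numpy(dtype=float)
    se_x = instruments["se_x"].to_numpy(dtype=float)
    b_y = instruments["b_y"].to_numpy(dtype=float)
    se_y = instruments["se_y"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = b_x + rng.normal(0.0, 1.0, k) * se_x
        by = b_y + rng.normal(0.0, 1.0, k) * se_y
        bx = np.where(bx == 0, 1e-12, bx)
        r = by / bx
        sr = se_y / np.abs(bx)
        wb = np.ones(k) if mode == "simple" else 1.0 / sr**2
        boots[i] = _mode_point(r, wb, _msad_bandwidth(r, sr, bandwidth_factor))
    se = float(boots.std(ddof=1))
    return MrEstimate(f"{mode}_mode", beta, se, _normal_p(beta, se), k)


def run_all_estimators(
    instruments: pd.DataFrame, seed: int = 0, n_boot: int = 1000
) -> list[MrEstimate]:
    """All applicable estimators for one exposure-outcome pair."""
    k = len(instruments)
    if k == 1:
        row = instruments.iloc[0]
        return [wald_ratio(row["b_x"], row["se_x"], row["b_y"], row["se_y"])]
    out = [ivw(instruments)]
    if k >= 3:
        slope, intercept = mr_egger(instruments)
        out += [slope, intercept]
        out.append(weighted_median(instruments, seed=seed, n_boot=n_boot))
        out.append(mode_estimators(instruments, "simple", seed=seed, n_boot=n_boot))
        out.append(mode_estimators(instruments, "weighted", seed=seed, n_boot=n_boot))
    return out
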