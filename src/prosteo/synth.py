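"""Synthetic longitudinal cohort and GWAS summary-statistic generators.

Every downstream stage of the pipeline (mixed models, meta-analysis, risk
scores, trajectory classes, survival, biological age, Mendelian randomization)
is exercised against data generated here, where the ground truth is known.

The cohort emulates a middle-aged population followed over three visits,
roughly three years apart, with:

- BMD at two sites (lumbar spine ``LS``, femoral neck ``FN``) that declines
  linearly in time with person-specific random level and slope;
- a subset of proteins causally shifting the BMD level (per-SD effects in BMD
  standard deviations);
- a subset of proteins linearly coupled to a latent biological age
  ``BA_true = CA + delta`` with ``delta ~ N(0, accel_sd^2)``; delta also
  steepens BMD decline so that accelerated agers reach osteoporosis sooner;
- left-censored missingness (the lowest per-protein quantile is removed,
  mimicking a detection limit) and a two-batch discovery/validation split with
  an optional per-protein batch shift;
- weakly correlated lifestyle/clinical covariates, a few of which confound
  both proteins and BMD.

Osteoporosis status is *not* simulated as a separate event process: it derives
from site-specific T-scores of the simulated BMD (see :mod:`prosteo.preprocess`),
which keeps the ground truth coherent across modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "generate_mr_summary"]

SITES = ("LS", "FN")

#: Young-adult DXA reference values (g/cm^2) in the style of Hologic lookup
#: tables; T = (BMD - mean) / sd.
DEFAULT_TSCORE_REF = {
    "LS": {"mean": 1.047, "sd": 0.110},
    "FN": {"mean": 0.858, "sd": 0.120},
}

# Baseline latent T-score means per site; chosen so a middle-aged cohort shows
# a realistic osteopenia burden and accumulates incident osteoporosis over
# ~6.6 years of follow-up.
_LEVEL_MEAN = {"LS": -1.0, "FN": -0.8}


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    Defaults mirror the scale of a two-batch Chinese cohort study: 3415
    participants (72% female, age 57.5 +/- 5.1 years), 413 serum proteins
    measured at 3 visits spaced 3.3 years apart, split into discovery and
    validation batches at a 1785:1630 ratio.
    """

    n_participants: int = 3415
    n_proteins: int = 413
    n_visits: int = 3
    visit_spacing_years: float = 3.3
    frac_female: float = 0.72
    age_mean: float = 57.5
    age_sd: float = 5.1
    #: number of proteins with a causal effect on BMD level
    n_bmd_proteins: int = 22
    #: per-SD protein effect on BMD, in BMD standard deviations
    bmd_effect_sd_per_sd: float = 0.3
    #: number of proteins linearly coupled to biological age
    n_age_proteins: int = 12
    #: correlation of each age-coupled protein with true biological age
    age_protein_r: float = 0.4
    #: SD of the true age acceleration delta (years)
    accel_sd: float = 5.0
    #: additional BMD decline (T-score units per year) per year of delta
    accel_slope_per_year: float = -0.02
    #: fraction of each protein's values removed as below detection limit
    missing_rate: float = 0.10
    #: SD of the per-protein additive shift applied to the validation batch
    batch_shift_sd: float = 0.10
    #: fraction of participants assigned to the discovery batch
    frac_discovery: float = 1785.0 / 3415.0
    #: strength of covariate confounding on proteins and BMD (0 disables)
    confound_strength: float = 0.1
    #: mean population BMD decline, T-score units per year
    bmd_slope_mean: float = -0.06
    bmd_slope_sd: float = 0.03
    #: visit-level BMD measurement noise, T-score units
    bmd_noise_sd: float = 0.10
    #: visit-level protein measurement noise, on the latent z scale
    protein_noise_sd: float = 0.35
    #: whether age/BMD protein sets may overlap
    allow_overlap: bool = False
    tscore_ref: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(DEFAULT_TSCORE_REF[s]) for s in SITES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 10:
            raise ValueError("n_participants must be >= 10")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if not self.allow_overlap and self.n_bmd_proteins + self.n_age_proteins > self.n_proteins:
            raise ValueError(
                "n_bmd_proteins + n_age_proteins exceeds n_proteins "
                "(set allow_overlap=True to permit shared proteins)"
            )
        for name in ("frac_female", "missing_rate", "frac_discovery"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "accel_sd", "visit_spacing_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        for s in SITES:
            if self.tscore_ref[s]["sd"] <= 0:
                raise ValueError(f"tscore_ref[{s}] sd must be > 0")


@dataclass
class GroundTruth:
    """True generating parameters, kept alongside the synthetic data."""

    bmd_protein_ids: list
    bmd_betas: dict  # protein id -> effect on BMD level (BMD SD per protein SD)
    age_protein_ids: list
    age_protein_params: dict  # protein id -> {"q": ..., "k": ..., "s": ...}
    ba_true: dict  # participant -> true biological age at baseline (years)
    delta: dict  # participant -> true age acceleration (years)
    bmd_slope: dict  # participant -> {"LS": slope, "FN": slope} (T units / year)
    theta_true: float | None = None  # MR causal effect, when applicable
    snp_pleiotropy: dict | None = None  # snp id -> alpha_i

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _simulate_covariates(rng: np.random.Generator, n: int, female: np.ndarray) -> pd.DataFrame:
    """Baseline lifestyle and clinical covariates, weakly inter-correlated."""
    bmi = rng.normal(23.3, 3.1, n)
    whr = np.clip(rng.normal(0.88, 0.08, n) + 0.01 * (bmi - 23.3) / 3.1, 0.6, 1.2)
    sbp = rng.normal(124, 17.7, n) + 1.5 * (bmi - 23.3)
    cov = pd.DataFrame(
        {
            "bmi": bmi,
            "whr": whr,
            "sbp": sbp,
            "dbp": rng.normal(78, 10.7, n) + 0.4 * (sbp - 124),
            "glucose": rng.normal(4.8, 1.0, n),
            "tc": rng.normal(5.4, 1.1, n),
            "tg": np.clip(rng.normal(1.6, 1.0, n), 0.2, None),
            "ldl": rng.normal(3.4, 0.9, n),
            "hdl": rng.normal(1.4, 0.35, n),
            "uric_acid": rng.normal(280, 110, n),
            "physical_activity": np.clip(rng.normal(41, 17, n), 0, None),
            "energy_intake": np.clip(rng.normal(1800, 450, n), 500, None),
            "carb_intake": np.clip(rng.normal(250, 75, n), 50, None),
            "fiber_intake": np.clip(rng.normal(12, 5, n), 1, None),
            "education": rng.integers(0, 3, n).astype(float),
            "income": rng.integers(0, 3, n).astype(float),
            "smoking": (rng.random(n) < np.where(female == 1, 0.03, 0.45)).astype(float),
            "alcohol": (rng.random(n) < 0.2).astype(float),
            "tea": (rng.random(n) < 0.5).astype(float),
            "calcium_supplement": (rng.random(n) < 0.2).astype(float),
            "multivitamin": (rng.random(n) < 0.15).astype(float),
        }
    )
    return cov


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic longitudinal cohort.

    Returns
    -------
    cohort : DataFrame
        Long format, one row per participant-visit: identifiers, visit time,
        sex, age, batch label, baseline covariates and BMD (g/cm^2) at the
        lumbar spine (``bmd_LS``) and femoral neck (``bmd_FN``).
    proteins : DataFrame
        (participant, visit)-indexed abundance matrix with NaN for values
        below the simulated detection limit.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    p = config.n_proteins

    participants = np.array([f"S{i:05d}" for i in range(1, n + 1)])
    protein_ids = [f"P{j:04d}" for j in range(1, p + 1)]

    female = (rng.random(n) < config.frac_female).astype(int)
    age0 = rng.normal(config.age_mean, config.age_sd, n)
    delta = rng.normal(0.0, config.accel_sd, n)
    ba_true = age0 + delta
    cov = _simulate_covariates(rng, n, female)

    # batch split at the configured ratio, deterministic given seed
    n_disc = int(round(n * config.frac_discovery))
    perm = rng.permutation(n)
    batch = np.where(np.isin(np.arange(n), perm[:n_disc]), "discovery", "validation")

    # --- protein matrix (per participant per visit) --------------------------
    idx_bmd = np.arange(config.n_bmd_proteins)
    if config.allow_overlap:
        idx_age = rng.choice(p, size=config.n_age_proteins, replace=False)
    else:
        idx_age = np.arange(config.n_bmd_proteins, config.n_bmd_proteins + config.n_age_proteins)

    times = np.arange(config.n_visits) * config.visit_spacing_years
    n_rows = n * config.n_visits

    # latent per-person protein z-scores, stable across visits apart from
    # visit-level measurement noise (abundances drift slowly in serum)
    z_person = rng.normal(0.0, 1.0, (n, p))
    if config.confound_strength > 0:
        # BMI confounds a handful of non-causal proteins
        bmi_z = (cov["bmi"].to_numpy() - 23.3) / 3.1
        n_conf = min(5, p)
        conf_idx = np.arange(p - n_conf, p)
        z_person[:, conf_idx] += config.confound_strength * bmi_z[:, None]

    # abundances on a positive intensity-like scale (lognormal around a
    # per-protein baseline), so a detection limit and half-minimum imputation
    # behave the way they do on real quantified intensities
    q_all = rng.uniform(8.0, 16.0, p)
    s_all = rng.uniform(0.2, 0.4, p)  # log-scale coefficient of variation

    # age-coupled proteins: x_j = q_j + k_j * BA_true + N(0, s_j^2), with s_j
    # set so corr(x_j, BA_true) equals age_protein_r
    sigma_ba = float(np.sqrt(config.age_sd**2 + config.accel_sd**2))
    k_signs = np.where(rng.random(config.n_age_proteins) < 0.5, -1.0, 1.0)
    k_age = k_signs * rng.uniform(0.03, 0.08, config.n_age_proteins)
    r = config.age_protein_r
    s_age = np.abs(k_age) * sigma_ba * np.sqrt(1.0 / r**2 - 1.0)

    abund = np.empty((n_rows, p))
    for v in range(config.n_visits):
        rows = slice(v * n, (v + 1) * n)
        noise = rng.normal(0.0, config.protein_noise_sd, (n, p)) \
            if config.protein_noise_sd > 0 else np.zeros((n, p))
        x = q_all * np.exp(s_all * (z_person + noise))
        # overwrite age-coupled columns with the explicit (linear) age model
        ba_v = ba_true + times[v]
        x[:, idx_age] = (
            q_all[idx_age]
            + k_age * ba_v[:, None]
            + rng.normal(0.0, 1.0, (n, config.n_age_proteins)) * s_age
        )
        abund[rows] = x

    # per-person causal-protein z-scores as seen by the BMD model (baseline)
    z_causal = z_person[:, idx_bmd]
    signs = np.where(np.arange(config.n_bmd_proteins) % 2 == 0, 1.0, -1.0)
    betas = -signs * config.bmd_effect_sd_per_sd  # half raise, half lower BMD

    # --- BMD: latent T-score linear growth model -----------------------------
    b_age = -0.05  # T units per year of baseline age
    b_sex = -0.25  # females lower
    b_bmi = 0.02 * config.confound_strength / 0.1 if config.confound_strength > 0 else 0.0

    fixed_var = (
        (b_age * config.age_sd) ** 2
        + b_sex**2 * config.frac_female * (1 - config.frac_female)
        + float(np.sum(betas**2))
    )
    sigma_u2 = max(0.05, 1.0 - fixed_var - config.bmd_noise_sd**2)

    bmd_cols = {}
    slope_truth: dict[str, dict[str, float]] = {pid: {} for pid in participants}
    for site in SITES:
        level = (
            _LEVEL_MEAN[site]
            + b_age * (age0 - config.age_mean)
            + b_sex * female
            + b_bmi * (cov["bmi"].to_numpy() - 23.3)
            + z_causal @ betas
            + rng.normal(0.0, np.sqrt(sigma_u2), n)
        )
        slope = (
            config.bmd_slope_mean
            + config.accel_slope_per_year * delta
            + rng.normal(0.0, config.bmd_slope_sd, n)
        )
        t_scores = np.concatenate(
            [
                level + slope * t + rng.normal(0.0, config.bmd_noise_sd, n)
                for t in times
            ]
        )
        ref = config.tscore_ref[site]
        bmd_cols[f"bmd_{site}"] = ref["mean"] + ref["sd"] * t_scores
        for i, pid in enumerate(participants):
            slope_truth[pid][site] = float(slope[i])

    # --- assemble long tables -------------------------------------------------
    visit_no = np.repeat(np.arange(1, config.n_visits + 1), n)
    time_years = np.repeat(times, n)
    cohort = pd.DataFrame(
        {
            "participant": np.tile(participants, config.n_visits),
            "visit": visit_no,
            "time_years": time_years,
            "age": np.tile(age0, config.n_visits) + time_years,
            "age_baseline": np.tile(age0, config.n_visits),
            "female": np.tile(female, config.n_visits),
            "batch": np.tile(batch, config.n_visits),
        }
    )
    for c in cov.columns:
        cohort[c] = np.tile(cov[c].to_numpy(), config.n_visits)
    for c, vals in bmd_cols.items():
        cohort[c] = vals
    cohort = cohort.sort_values(["participant", "visit"], kind="stable").reset_index(drop=True)

    proteins = pd.DataFrame(
        abund,
        index=pd.MultiIndex.from_arrays(
            [np.tile(participants, config.n_visits), visit_no],
            names=["participant", "visit"],
        ),
        columns=protein_ids,
    ).sort_index()

    # validation-batch shift (per-protein multiplicative intensity bias, the
    # residual of imperfect cross-run normalization), applied before censoring
    if config.batch_shift_sd > 0:
        shift = np.exp(rng.normal(0.0, config.batch_shift_sd, p))
        val_participants = set(participants[batch == "validation"])
        mask = proteins.index.get_level_values("participant").isin(val_participants)
        proteins.loc[mask] = proteins.loc[mask].to_numpy() * shift

    # left-censored missingness: each measurement batch has its own detection
    # limit, so the lowest missing_rate fraction is removed per protein within
    # each batch
    if config.missing_rate > 0:
        vals = proteins.to_numpy()
        row_batch = pd.Series(batch, index=participants).loc[
            proteins.index.get_level_values("participant")
        ].to_numpy()
        for b in ("discovery", "validation"):
            rows = np.where(row_batch == b)[0]
            if rows.size == 0:
                continue
            k = int(round(config.missing_rate * rows.size))
            if k > 0:
                order = np.argsort(vals[rows], axis=0, kind="stable")
                cut = rows[order[:k, :]]
                cols = np.broadcast_to(np.arange(p), cut.shape)
                vals[cut.ravel(), cols.ravel()] = np.nan
        proteins = pd.DataFrame(vals, index=proteins.index, columns=proteins.columns)

    truth = GroundTruth(
        bmd_protein_ids=[protein_ids[j] for j in idx_bmd],
        bmd_betas={protein_ids[j]: float(betas[i]) for i, j in enumerate(idx_bmd)},
        age_protein_ids=[protein_ids[j] for j in idx_age],
        age_protein_params={
            protein_ids[j]: {"q": float(q_all[j]), "k": float(k_age[i]), "s": float(s_age[i])}
            for i, j in enumerate(idx_age)
        },
        ba_true={pid: float(b) for pid, b in zip(participants, ba_true)},
        delta={pid: float(d) for pid, d in zip(participants, delta)},
        bmd_slope=slope_truth,
    )
    return cohort, proteins, truth


def generate_trajectory_classes(
    n_per_class: int | list[int],
    intercepts: list[float],
    slopes: list[float],
    sigma: float,
    times: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted latent-class growth data for trajectory-model validation.

    Returns ``(y, labels)`` with ``y`` of shape (n_total, n_visits) generated
    as ``a_k + b_k t + N(0, sigma^2)`` per class.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if np.isscalar(n_per_class) or isinstance(n_per_class, int):
        n_per_class = [int(n_per_class)] * len(intercepts)
    blocks, labels = [], []
    for k, (a, b, nk) in enumerate(zip(intercepts, slopes, n_per_class)):
        mean = a + b * times
        blocks.append(mean + rng.normal(0.0, sigma, (nk, times.size)))
        labels.append(np.full(nk, k))
    return np.vstack(blocks), np.concatenate(labels)


_ALLELES = np.array(list("ACGT"))


def generate_mr_summary(
    n_snps: int,
    theta_true: float,
    pleiotropy_sd: float,
    seed: int,
    *,
    frac_pleiotropic: float = 1.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_on_weakest: bool = False,
    se_x: float = 0.008,
    se_y_range: tuple[float, float] = (0.01, 0.03),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate harmonizable two-sample GWAS summary statistics.

    Per SNP *i* the true instrument effect ``gamma_i ~ U(0.06, 0.25)`` (random
    sign); the observed exposure effect is ``b_X = gamma_i + N(0, se_x^2)`` and
    the outcome effect is ``b_Y = theta_true * gamma_i + alpha_i + N(0, se_y^2)``
    with pleiotropy ``alpha_i ~ N(pleiotropy_mean, pleiotropy_sd^2)`` applied to
    a ``frac_pleiotropic`` fraction of SNPs (directional pleiotropy with
    ``pleiotropy_mean != 0`` makes a fraction of instruments invalid, the
    scenario where median/mode estimators outperform IVW).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if pleiotropy_sd < 0:
        raise ValueError("pleiotropy_sd must be >= 0")
    rng = np.random.default_rng(seed)

    # instruments oriented so the effect allele raises the exposure, the usual
    # reporting convention for published pQTL instruments
    gamma = rng.uniform(0.06, 0.25, n_snps)
    b_x = gamma + rng.normal(0.0, se_x, n_snps)
    se_y = rng.uniform(*se_y_range, n_snps)
    alpha = np.zeros(n_snps)
    n_pleio = int(round(frac_pleiotropic * n_snps))
    if n_pleio > 0 and (pleiotropy_sd > 0 or pleiotropy_mean != 0):
        if pleiotropy_on_weakest:
            # pleiotropy on the weakest instruments: the valid SNPs then hold
            # the majority of the inverse-variance weight, the regime where
            # median-based estimators stay consistent while IVW does not
            which = np.argsort(np.abs(gamma))[:n_pleio]
        else:
            which = rng.choice(n_snps, size=n_pleio, replace=False)
        alpha[which] = rng.normal(pleiotropy_mean, pleiotropy_sd, n_pleio)
    b_y = theta_true * gamma + alpha + rng.normal(0.0, 1.0, n_snps) * se_y

    ea_idx = rng.integers(0, 4, n_snps)
    oa_idx = (ea_idx + rng.integers(1, 4, n_snps)) % 4
    from scipy import stats

    p_x = 2.0 * stats.norm.sf(np.abs(b_x) / se_x)
    instruments = pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(n_snps)],
            "effect_allele": _ALLELES[ea_idx],
            "other_allele": _ALLELES[oa_idx],
            "b_x": b_x,
            "se_x": se_x,
            "p_x": p_x,
            "b_y": b_y,
            "se_y": se_y,
            "eaf": rng.uniform(0.05, 0.95, n_snps),
        }
    )
    truth = GroundTruth(
        bmd_protein_ids=[],
        bmd_betas={},
        age_protein_ids=[],
        age_protein_params={},
        ba_true={},
        delta={},
        bmd_slope={},
        theta_true=theta_true,
        snp_pleiotropy={row: float(a) for row, a in zip(instruments["snp"], alpha)},
    )
    return instruments, truth
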