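"""End-to-end pipeline driver.

Runs simulate -> preprocess -> select -> assoc -> meta -> prs -> trajectory ->
survival -> bioage -> mr on a synthetic cohort, each stage individually
skippable, and writes per-stage outputs plus a JSON run manifest. The pipeline
is a thin orchestration of the library modules; every stage can equally be
driven from Python.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import bioage as bioage_mod
from . import mr as mr_mod
from . import preprocess as pp
from . import score as score_mod
from . import select as select_mod
from . import surv as surv_mod
from . import synth
from . import traj as traj_mod

logger = logging.getLogger("prosteo")

STAGES = [
    "simulate",
    "preprocess",
    "select",
    "assoc",
    "meta",
    "prs",
    "trajectory",
    "survival",
    "bioage",
    "mr",
]

#: covariate tiers for survival models: demographics; + lifestyle/diet;
#: + clinical biochemistry
COVARIATE_TIERS = {
    "model1": ["age_baseline", "female"],
    "model2": [
        "age_baseline", "female", "bmi", "whr", "education", "income", "smoking",
        "alcohol", "tea", "physical_activity", "energy_intake", "carb_intake",
        "fiber_intake", "calcium_supplement", "multivitamin",
    ],
    "model3": [
        "age_baseline", "female", "bmi", "whr", "education", "income", "smoking",
        "alcohol", "tea", "physical_activity", "energy_intake", "carb_intake",
        "fiber_intake", "calcium_supplement", "multivitamin", "sbp", "dbp",
        "glucose", "tc", "tg", "ldl", "hdl", "uric_acid",
    ],
}


@dataclass
class PipelineConfig:
    """Desk-scale pipeline configuration (overridable per stage)."""

    synth: synth.SynthConfig = field(
        default_factory=lambda: synth.SynthConfig(
            n_participants=800, n_proteins=60, n_bmd_proteins=8, n_age_proteins=12
        )
    )
    seed: int = 0
    out_dir: str | None = None
    stages: list = field(default_factory=lambda: list(STAGES))
    # stage parameters
    train_frac: float = 0.7
    lasso_folds: int = 10
    p_threshold: float = 0.05
    i2_threshold: float = 30.0
    assoc_covariates: list = field(
        default_factory=lambda: ["age_baseline", "female", "bmi", "whr"]
    )
    max_classes: int = 5
    appa_threshold: float = 0.7
    traj_restarts: int = 10
    rcs_knots: int = 4
    kdm_min_abs_r: float = 0.1
    kdm_max_pairwise_r: float = 0.7
    surv_covariates: list = field(default_factory=lambda: ["age_baseline", "female"])
    mr_n_snps: int = 50
    mr_theta_true: float = 0.5
    mr_pleiotropy_sd: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "synth" in raw:
            synth_known = {f.name for f in dataclasses.fields(synth.SynthConfig)}
            bad = set(raw["synth"]) - synth_known
            if bad:
                raise ValueError(f"unknown synth config key(s): {sorted(bad)}")
            raw["synth"] = synth.SynthConfig(**raw["synth"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _baseline_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["visit"] == 1].set_index("participant")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the result bundle.

    Stage dependencies are checked: requesting a downstream stage without its
    upstream artifact raises a ``ValueError`` naming the missing input.
    """
    t_start = time.time()
    bundle: dict = {"manifest": {"seed": config.seed, "stages": [], "params": {}}}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def record(stage, **info):
        bundle["manifest"]["stages"].append({"stage": stage, **info})
        logger.info("stage %s done: %s", stage, info)

    # ------------------------------------------------------------- simulate
    if "simulate" in config.stages:
        cfg = dataclasses.replace(config.synth, seed=config.seed)
        cohort, proteins, truth = synth.generate_cohort(cfg)
        bundle.update(cohort=cohort, proteins=proteins, truth=truth)
        mr_table, mr_truth = synth.generate_mr_summary(
            config.mr_n_snps, config.mr_theta_true, config.mr_pleiotropy_sd,
            seed=config.seed + 1,
        )
        bundle.update(mr_table=mr_table, mr_truth=mr_truth)
        record("simulate", n_participants=cfg.n_participants, n_proteins=cfg.n_proteins,
               n_rows=len(proteins))
        if out_dir:
            from .io import write_cohort, write_gwas_summary

            write_cohort(cohort, proteins, out_dir / "synthetic")
            truth.to_json(out_dir / "ground_truth.json")
            write_gwas_summary(mr_table, out_dir / "mr_summary.tsv")

    # ----------------------------------------------------------- preprocess
    if "preprocess" in config.stages:
        _require(bundle, "cohort", "preprocess")
        cohort, proteins = bundle["cohort"], bundle["proteins"]
        imputed = pp.impute_half_min(proteins)
        # standardize per batch, parameters fit on that batch's baseline rows
        base = _baseline_frame(cohort)
        z_parts = []
        for batch in ("discovery", "validation"):
            pids = base.index[base["batch"] == batch]
            rows = imputed.index.get_level_values("participant").isin(pids)
            block = imputed.loc[rows]
            fit_rows = block.index[block.index.get_level_values("visit") == 1]
            z_block, _ = pp.standardize(block, fit_on=fit_rows)
            z_parts.append(z_block)
        protein_z = pd.concat(z_parts).sort_index()
        bundle["protein_z"] = protein_z
        bundle["protein_imputed"] = imputed

        # T-score status per site per visit
        statuses = {}
        for site in synth.SITES:
            ref = config.synth.tscore_ref[site]
            t, status = pp.tscore_classify(
                cohort[f"bmd_{site}"].to_numpy(), ref["mean"], ref["sd"]
            )
            df = cohort[["participant", "visit", "time_years"]].copy()
            df["tscore"] = t
            df["status"] = status
            statuses[site] = df
        bundle["statuses"] = statuses

        # ever-osteoporosis labels per participant per site
        labels = {}
        for site in synth.SITES:
            ever = statuses[site].groupby("participant")["status"].apply(
                lambda s: bool((s == "osteoporosis").any())
            )
            labels[site] = ever.astype(int)
        bundle["labels"] = labels

        # fold change at baseline (imputed abundances), cases = ever-OP at LS
        base_rows = imputed.index[imputed.index.get_level_values("visit") == 1]
        base_mat = imputed.loc[base_rows]
        lab = labels["LS"].reindex(base_mat.index.get_level_values("participant"))
        bundle["fold_change"] = pp.fold_change(
            base_mat, base_mat.index[lab.to_numpy() == 1], base_mat.index[lab.to_numpy() == 0]
        )
        base_z = protein_z.loc[base_rows]
        batch_labels = base.loc[base_z.index.get_level_values("participant"), "batch"].to_numpy()
        pca = pp.pca_batch_check(base_z, batch_labels)
        bundle["pca_check"] = {
            "pc1_batch_gap_sd": pca["pc1_batch_gap_sd"],
            "cumulative_variance": pca["cumulative_variance"].tolist(),
        }
        # within-person BMD change, first vs last visit
        wide = cohort.pivot_table(index="participant", columns="visit", values="bmd_LS")
        first, last = wide.columns.min(), wide.columns.max()
        ok = wide[[first, last]].dropna()
        bundle["paired_t_ls"] = pp.paired_t(ok[last], ok[first])
        record("preprocess", n_imputed=int(proteins.isna().sum().sum()),
               pc1_gap=float(pca["pc1_batch_gap_sd"]))

    # --------------------------------------------------------------- select
    if "select" in config.stages:
        _require(bundle, "protein_z", "select")
        cohort = bundle["cohort"]
        base = _baseline_frame(cohort)
        base_rows = bundle["protein_z"].index.get_level_values("visit") == 1
        base_z = bundle["protein_z"].loc[base_rows]
        base_z.index = base_z.index.get_level_values("participant")
        results = {}
        for site in synth.SITES:
            y = bundle["labels"][site]
            disc = base.index[base["batch"] == "discovery"]
            val = base.index[base["batch"] == "validation"]
            train_ids, test_ids = select_mod.split_discovery(
                disc.to_numpy(), config.train_frac, seed=config.seed + 2
            )
            Xtr, ytr = base_z.loc[train_ids], y.loc[train_ids].to_numpy()
            Xte, yte = base_z.loc[test_ids], y.loc[test_ids].to_numpy()
            Xva, yva = base_z.loc[val], y.loc[val].to_numpy()
            results[site] = {
                "gbm_shap": select_mod.select_by_shap(
                    Xtr, ytr, seed=config.seed + 3, test=(Xte, yte), validation=(Xva, yva)
                ),
                "lasso": select_mod.select_by_lasso(
                    Xtr, ytr, n_folds=config.lasso_folds, seed=config.seed + 3,
                    test=(Xte, yte), validation=(Xva, yva)
                ),
            }
        bundle["selection"] = results
        record("select", **{
            f"{site}_{m}_auc_val": round(results[site][m].auc_validation, 3)
            for site in synth.SITES for m in ("gbm_shap", "lasso")
        })

    # ---------------------------------------------------------------- assoc
    if "assoc" in config.stages:
        _require(bundle, "protein_z", "assoc")
        cohort = bundle["cohort"]
        base = _baseline_frame(cohort)
        base_rows = bundle["protein_z"].index.get_level_values("visit") == 1
        base_z = bundle["protein_z"].loc[base_rows]
        base_z.index = base_z.index.get_level_values("participant")
        estimates: dict[str, dict[str, list]] = {s: {} for s in synth.SITES}
        for site in synth.SITES:
            for batch in ("discovery", "validation"):
                pids = base.index[base["batch"] == batch]
                sub = cohort[cohort["participant"].isin(pids)].copy()
                bmd = sub[f"bmd_{site}"]
                sub["bmd_z"] = (bmd - bmd.mean()) / bmd.std(ddof=1)
                cov = base.loc[pids, config.assoc_covariates]
                for protein in base_z.columns:
                    est = assoc_mod.fit_lmm(
                        base_z.loc[pids, protein], sub, cov,
                        protein=protein, cohort=batch, site=site,
                    )
                    estimates[site].setdefault(protein, []).append(est)
        bundle["assoc"] = estimates
        record("assoc", n_models=sum(len(v) for s in estimates.values() for v in s.values()))

    # ----------------------------------------------------------------- meta
    if "meta" in config.stages:
        _require(bundle, "assoc", "meta")
        metas = []
        for site in synth.SITES:
            for protein, ests in bundle["assoc"][site].items():
                metas.append(assoc_mod.meta_random_effects(ests))
        flagged = assoc_mod.flag_significant(
            metas, p_threshold=config.p_threshold, i2_threshold=config.i2_threshold
        )
        bundle["meta"] = metas
        bundle["meta_flagged"] = flagged
        if out_dir:
            pd.DataFrame([dataclasses.asdict(m) for m in metas]).to_csv(
                out_dir / "meta_estimates.tsv", sep="\t", index=False
            )
        record("meta", n_flagged=len(flagged))

    # ------------------------------------------------------------------ prs
    if "prs" in config.stages:
        _require(bundle, "meta_flagged", "prs")
        base_rows = bundle["protein_z"].index.get_level_values("visit") == 1
        base_z = bundle["protein_z"].loc[base_rows]
        base_z.index = base_z.index.get_level_values("participant")
        base = _baseline_frame(bundle["cohort"])
        prs = {}
        for site in synth.SITES:
            weights = {
                m.protein: m.beta_pooled for m in bundle["meta_flagged"] if m.site == site
            }
            if not weights:
                logger.warning("no flagged protein for site %s; PRS skipped", site)
                continue
            scores = score_mod.build_prs(weights, base_z)
            q, degenerate = score_mod.prs_quartiles(scores["standardized"].to_numpy())
            scores["quartile"] = q
            bmd = base[f"bmd_{site}"]
            glm_lin = score_mod.fit_glm_cross(
                scores["standardized"].to_numpy(),
                ((bmd - bmd.mean()) / bmd.std(ddof=1)).loc[scores.index].to_numpy(),
                base.loc[scores.index, config.assoc_covariates],
                family="linear",
            )
            prs[site] = {"weights": weights, "scores": scores, "glm_linear": glm_lin,
                         "degenerate_quartiles": degenerate}
        bundle["prs"] = prs
        record("prs", sites=list(prs))

    # ------------------------------------------------------------ trajectory
    if "trajectory" in config.stages:
        _require(bundle, "cohort", "trajectory")
        cohort = bundle["cohort"]
        traj = {}
        for site in synth.SITES:
            sub = cohort[["participant", "time_years"]].copy()
            bmd = cohort[f"bmd_{site}"]
            sub["bmd_z"] = (bmd - bmd.mean()) / bmd.std(ddof=1)
            fits = []
            for k in range(1, config.max_classes + 1):
                fits.append(
                    traj_mod.fit_lctm(
                        sub, k, seed=config.seed + 4, n_restarts=config.traj_restarts
                    )
                )
            best = traj_mod.select_classes(fits, appa_threshold=config.appa_threshold)
            entry = {
                "best": best,
                "bic_table": {f.n_classes: f.bic_ for f in fits},
                "anova": {},
            }
            # protein means across classes, for the meta-flagged proteins
            if "meta_flagged" in bundle and best.n_classes >= 2:
                base_rows = bundle["protein_z"].index.get_level_values("visit") == 1
                base_z = bundle["protein_z"].loc[base_rows]
                base_z.index = base_z.index.get_level_values("participant")
                assign = pd.Series(best.labels_, index=best.participants_)
                counts = assign.value_counts()
                if (counts >= 2).all():
                    for m in bundle["meta_flagged"]:
                        if m.site != site or m.protein in entry["anova"]:
                            continue
                        x = base_z[m.protein].reindex(assign.index).to_numpy()
                        entry["anova"][m.protein] = traj_mod.anova_across_classes(
                            x, assign.to_numpy()
                        )
            traj[site] = entry
        bundle["trajectory"] = traj
        record("trajectory", classes={s: traj[s]["best"].n_classes for s in traj})

    # -------------------------------------------------------------- survival
    if "survival" in config.stages:
        _require(bundle, "statuses", "survival")
        base = _baseline_frame(bundle["cohort"])
        surv = {}
        for site in synth.SITES:
            records, log = surv_mod.make_survival_records(bundle["statuses"][site])
            for c in set(config.surv_covariates) | set(COVARIATE_TIERS["model3"]):
                records[c] = records["participant"].map(base[c])
            entry = {"records": records, "log": log}
            if "prs" in bundle and site in bundle["prs"]:
                scores = bundle["prs"][site]["scores"]
                records["prs"] = records["participant"].map(scores["standardized"])
                records["prs_quartile"] = records["participant"].map(
                    pd.Series(scores["quartile"].to_numpy(), index=scores.index)
                )
                entry["cox_prs"] = surv_mod.fit_cox(
                    records.dropna(subset=["prs"]), "prs", config.surv_covariates
                )
                ok = records.dropna(subset=["prs_quartile"])
                entry["quartile_hr"] = surv_mod.quartile_hr(
                    ok, ok["prs_quartile"].to_numpy(), config.surv_covariates
                )
                entry["rcs_curve"] = surv_mod.rcs_dose_response(
                    records.dropna(subset=["prs"]), "prs", config.surv_covariates,
                    n_knots=config.rcs_knots,
                )
            surv[site] = entry
        bundle["survival"] = surv
        record("survival", events={s: surv[s]["log"]["n_events"] for s in surv})

    # ---------------------------------------------------------------- bioage
    if "bioage" in config.stages:
        _require(bundle, "protein_z", "bioage")
        base = _baseline_frame(bundle["cohort"])
        base_rows = bundle["protein_z"].index.get_level_values("visit") == 1
        base_z = bundle["protein_z"].loc[base_rows]
        base_z.index = base_z.index.get_level_values("participant")
        ca = base.loc[base_z.index, "age_baseline"].to_numpy()
        panel = bioage_mod.select_age_proteins(
            base_z, ca, max_pairwise_r=config.kdm_max_pairwise_r,
            min_abs_r=config.kdm_min_abs_r,
        )
        model = bioage_mod.fit_kdm(base_z[panel], ca)
        ages = model.predict(base_z[panel], ca)
        entry = {"panel": panel, "model": model, "ages": ages, "cox": {}}
        if "survival" in bundle:
            for site in synth.SITES:
                records = bundle["survival"][site]["records"]
                entry["cox"][site] = {
                    "proage": bioage_mod.bioage_survival(
                        ages, records, {"model1": COVARIATE_TIERS["model1"]},
                        exposure="ba_ec",
                    )["model1"],
                    "accel": bioage_mod.bioage_survival(
                        ages, records, {"model1": COVARIATE_TIERS["model1"]},
                        exposure="accel",
                    )["model1"],
                }
        bundle["bioage"] = entry
        if out_dir:
            model.to_json(out_dir / "kdm_model.json")
            ages.to_csv(out_dir / "bioages.tsv", sep="\t", float_format="%.17g")
        record("bioage", panel_size=len(panel), s_ba=round(model.s_ba_, 3))

    # -------------------------------------------------------------------- mr
    if "mr" in config.stages:
        _require(bundle, "mr_table", "mr")
        table = bundle["mr_table"]
        exposure = table.rename(columns={"b_x": "beta", "se_x": "se", "p_x": "pval"})[
            ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "eaf"]
        ]
        outcome = table.rename(columns={"b_y": "beta", "se_y": "se"})[
            ["snp", "effect_allele", "other_allele", "beta", "se", "eaf"]
        ]
        harmonized = mr_mod.harmonize(exposure, outcome)
        instruments = mr_mod.filter_instruments(harmonized)
        estimates = mr_mod.run_all_estimators(instruments, seed=config.seed + 5)
        bundle["mr"] = {"instruments": instruments, "estimates": estimates}
        if out_dir:
            pd.DataFrame([dataclasses.asdict(e) for e in estimates]).drop(
                columns=["extras"]
            ).to_csv(out_dir / "mr_estimates.tsv", sep="\t", index=False)
        record("mr", n_snps=len(instruments),
               ivw=round([e for e in estimates if e.method == "ivw"][0].beta, 3))

    bundle["manifest"]["runtime_s"] = round(time.time() - t_start, 1)
    bundle["manifest"]["params"] = {
        "train_frac": config.train_frac,
        "p_threshold": config.p_threshold,
        "i2_threshold": config.i2_threshold,
        "appa_threshold": config.appa_threshold,
        "gwas_p_threshold": mr_mod.GWAS_P_THRESHOLD,
        "max_classes": config.max_classes,
    }
    if out_dir:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=1, default=str)
    return bundle


def _require(bundle: dict, key: str, stage: str) -> None:
    if key not in bundle:
        raise ValueError(f"stage '{stage}' requires upstream artifact '{key}'")
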