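"""Readers and writers for cohort, protein-matrix and GWAS summary tables.

Cohort and protein tables travel as TSV with one header row; a missing protein
abundance is an empty cell. Ground truth and fitted models serialize to JSON.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_cohort", "write_cohort", "read_gwas_summary", "write_gwas_summary"]

COHORT_REQUIRED = ["participant", "visit", "time_years", "age", "female", "batch"]
COHORT_KNOWN = COHORT_REQUIRED + [
    "age_baseline", "bmd_LS", "bmd_FN", "bmi", "whr", "sbp", "dbp", "glucose",
    "tc", "tg", "ldl", "hdl", "uric_acid", "physical_activity", "energy_intake",
    "carb_intake", "fiber_intake", "education", "income", "smoking", "alcohol",
    "tea", "calcium_supplement", "multivitamin", "treated",
]
GWAS_REQUIRED = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]


class MalformedRowsWarning(UserWarning):
    pass


def write_cohort(cohort: pd.DataFrame, proteins: pd.DataFrame, prefix) -> tuple[Path, Path]:
    """Write the cohort table and protein matrix as ``<prefix>.cohort.tsv`` /
    ``<prefix>.proteins.tsv`` (floats at 17 significant digits, empty cell =
    missing)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cohort_path = prefix.with_suffix(".cohort.tsv")
    proteins_path = prefix.with_suffix(".proteins.tsv")
    cohort.to_csv(cohort_path, sep="\t", index=False, float_format="%.17g")
    proteins.reset_index().to_csv(proteins_path, sep="\t", index=False, float_format="%.17g")
    return cohort_path, proteins_path


def read_cohort(cohort_path, proteins_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort table and protein matrix written by :func:`write_cohort`.

    Missing protein cells become NaN (the missingness mask). Rows with
    non-numeric abundance cells are dropped with a :class:`MalformedRowsWarning`
    naming the offending line numbers; a missing mandatory cohort column raises.
    """
    cohort = pd.read_csv(cohort_path, sep="\t")
    missing_cols = [c for c in COHORT_REQUIRED if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing mandatory column(s): {missing_cols}")
    unknown = [c for c in cohort.columns if c not in COHORT_KNOWN]
    if unknown:
        warnings.warn(f"ignoring unknown cohort column(s): {unknown}", UserWarning,
                      stacklevel=2)
        cohort = cohort.drop(columns=unknown)

    raw = pd.read_csv(proteins_path, sep="\t", dtype=str)
    for c in ("participant", "visit"):
        if c not in raw.columns:
            raise ValueError(f"protein matrix missing mandatory column: {c}")
    protein_cols = [c for c in raw.columns if c not in ("participant", "visit")]
    values = raw[protein_cols].apply(pd.to_numeric, errors="coerce")
    # distinguish truly empty cells (missing) from malformed text
    malformed = values.isna() & raw[protein_cols].notna() & (raw[protein_cols] != "")
    bad_rows = malformed.any(axis=1)
    if bad_rows.any():
        lines = [int(i) + 2 for i in raw.index[bad_rows]]  # +2: header + 1-based
        warnings.warn(
            f"dropped {bad_rows.sum()} row(s) with non-numeric abundance cells "
            f"(file lines {lines})",
            MalformedRowsWarning,
            stacklevel=2,
        )
        raw = raw[~bad_rows]
        values = values[~bad_rows]
    proteins = values.copy()
    proteins.index = pd.MultiIndex.from_arrays(
        [raw["participant"].to_numpy(), raw["visit"].astype(int).to_numpy()],
        names=["participant", "visit"],
    )
    return cohort, proteins.sort_index()


def read_gwas_summary(path) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV (snp, alleles, beta, se, pval[, eaf])."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS summary table missing column(s): {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return df


def write_gwas_summary(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
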