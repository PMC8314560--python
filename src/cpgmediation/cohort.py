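"""Cohort table schema, validation, I/O and design-matrix encoding.

A cohort is a tidy :class:`pandas.DataFrame`, one row per patient, with

* ``patient_id`` — unique string id;
* ``arm`` — randomized arm, ``early-PN`` or ``late-PN`` (never missing);
* thirteen baseline covariates (age, center, sex, race, geographic origin,
  language, malignancy, diabetes, syndrome, admission diagnosis, PIM3, PeLOD,
  STRONGkids), never missing;
* one beta-value column in [0, 1] per CpG site of the panel;
* three continuous behavioral outcomes (``internalizing``, ``externalizing``,
  ``total``), the only columns in which NaN is legal (missing outcome).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ARMS = ("early-PN", "late-PN")
OUTCOMES = ("internalizing", "externalizing", "total")

#: Fixed category levels; the integer encoding used for modelling follows this
#: order, so encodings are deterministic across runs and machines.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "arm": ARMS,
    "center": ("Leuven", "Rotterdam", "Edmonton"),
    "sex": ("Male", "Female"),
    "race": ("White", "Other", "Unknown"),
    "geographic_origin": ("Western", "Non-western", "Unknown"),
    "language": ("Dutch", "English", "Other"),
    "diagnosis": (
        "Surgical-Cardiac",
        "Surgical-Other",
        "Medical-Neurologic",
        "Medical-Respiratory",
        "Medical-Other",
    ),
    "strongkids": ("Medium", "High"),
}

BINARY_COVARIATES = ("malignancy", "diabetes", "syndrome")
CONTINUOUS_COVARIATES = ("age", "pim3", "pelod")
CATEGORICAL_COVARIATES = (
    "center",
    "sex",
    "race",
    "geographic_origin",
    "language",
    "diagnosis",
    "strongkids",
)
#: Baseline risk factors, in the fixed order used in design matrices.
COVARIATES = (
    "age",
    "center",
    "sex",
    "race",
    "geographic_origin",
    "language",
    "malignancy",
    "diabetes",
    "syndrome",
    "diagnosis",
    "pim3",
    "pelod",
    "strongkids",
)

INTERVENTION = "arm"


class CohortSchemaError(ValueError):
    """A cohort table violates the documented schema."""


def cpg_columns(cohort: pd.DataFrame) -> list[str]:
    """CpG beta-value columns, i.e. every column starting with ``cg``."""
    return [c for c in cohort.columns if c.startswith("cg")]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema; return it unchanged.

    Raises :class:`CohortSchemaError` naming the first offending column (and
    row, for range errors).
    """
    fixed = ["patient_id", "arm", *COVARIATES]
    for col in fixed + list(OUTCOMES):
        if col not in cohort.columns:
            raise CohortSchemaError(f"missing required column: {col!r}")
    if cohort["patient_id"].duplicated().any():
        dup = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortSchemaError(f"duplicate patient_id: {dup!r}")
    if cohort["arm"].isna().any():
        row = int(np.flatnonzero(cohort["arm"].isna())[0])
        raise CohortSchemaError(f"missing arm in row {row}")
    bad_arm = set(cohort["arm"].dropna()) - set(ARMS)
    if bad_arm:
        raise CohortSchemaError(f"unknown arm labels: {sorted(bad_arm)}")
    for col in COVARIATES:
        if cohort[col].isna().any():
            row = int(np.flatnonzero(cohort[col].isna())[0])
            raise CohortSchemaError(f"missing covariate {col!r} in row {row}")
    for col in CATEGORICAL_COVARIATES:
        bad = set(cohort[col].astype(str)) - set(CATEGORICAL_LEVELS[col])
        if bad:
            raise CohortSchemaError(f"unknown levels in {col!r}: {sorted(bad)}")
    for col in cpg_columns(cohort):
        vals = cohort[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            row = int(np.flatnonzero(np.isnan(vals))[0])
            raise CohortSchemaError(f"missing beta-value in column {col!r}, row {row}")
        out = (vals < 0.0) | (vals > 1.0)
        if out.any():
            row = int(np.flatnonzero(out)[0])
            raise CohortSchemaError(
                f"beta-value out of [0, 1] in column {col!r}, row {row}: {vals[row]}"
            )
    return cohort


def outcome_missing_flags(cohort: pd.DataFrame) -> pd.DataFrame:
    """Boolean per-outcome missingness flags (True = missing)."""
    return cohort[list(OUTCOMES)].isna()


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (missing outcomes as empty cells)."""
    validate_cohort(cohort)
    cohort.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV/TSV (delimiter sniffed from extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cohort = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    return validate_cohort(cohort)


def encode_design(
    cohort: pd.DataFrame,
    *,
    include_cpg: bool = True,
    include_intervention: bool = True,
    cpg_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Numeric design matrix for tree models.

    Categorical covariates are integer-encoded following the fixed level
    order in :data:`CATEGORICAL_LEVELS` (trees are insensitive to the coding
    beyond determinism); the intervention is coded early-PN=1, late-PN=0.
    Column order: covariates, then ``arm`` (if requested), then CpGs.
    """
    cols: dict[str, np.ndarray] = {}
    for col in COVARIATES:
        if col in CATEGORICAL_COVARIATES:
            levels = CATEGORICAL_LEVELS[col]
            codes = pd.Categorical(cohort[col], categories=levels).codes
            cols[col] = codes.astype(float)
        else:
            cols[col] = cohort[col].to_numpy(dtype=float)
    if include_intervention:
        cols[INTERVENTION] = (cohort["arm"] == "early-PN").to_numpy(dtype=float)
    if include_cpg:
        for col in cpg_ids if cpg_ids is not None else cpg_columns(cohort):
            cols[col] = cohort[col].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)
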