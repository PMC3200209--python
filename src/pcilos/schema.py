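"""Cohort table schema and package-wide error types.

A cohort is a :class:`pandas.DataFrame` with one row per PCI procedure.
Columns, their domains and the CSV encoding (booleans as 0/1, categories as
lowercase tokens) are fixed here so that every module agrees on them.
"""

from __future__ import annotations

import pandas as pd

#: Ordered risk categories shared by all three stratifiers.
RISK_CLASSES: tuple[str, ...] = ("very_low", "low", "moderate", "high", "very_high")

SEX_LEVELS = ("male", "female")
HF_LEVELS = ("none", "past", "current")
MI_LEVELS = ("none", "lt6h_no_st", "6_23h_no_st", "lt24h_stent_thrombosis", "d1_14", "gt14d")
HEMO_LEVELS = ("stable", "unstable", "shock")

#: column -> admissible values (None for numeric columns).
COHORT_COLUMNS: dict[str, tuple[str, ...] | None] = {
    "age": None,
    "sex": SEX_LEVELS,
    "heart_failure": HF_LEVELS,
    "nyha_class_3_4": None,
    "creatinine_gt_2_5": None,
    "dialysis": None,
    "ejection_fraction": None,  # percent, may be missing (NaN)
    "mi_timing": MI_LEVELS,
    "peripheral_arterial_disease": None,
    "left_main_disease": None,
    "multivessel_disease": None,
    "angiographic_thrombus": None,
    "hemodynamic_state": HEMO_LEVELS,
    "urgent_emergent": None,
    "provider_id": None,
    "los_days": None,
    "complication": None,
}

FLAG_COLUMNS = (
    "nyha_class_3_4",
    "creatinine_gt_2_5",
    "dialysis",
    "peripheral_arterial_disease",
    "left_main_disease",
    "multivessel_disease",
    "angiographic_thrombus",
    "urgent_emergent",
    "complication",
)


class SchemaError(ValueError):
    """A cohort table violates the documented schema."""


class ConfigError(ValueError):
    """An invalid generator or study configuration."""


class CalibrationError(ValueError):
    """The requested LOS calibration has no solution in the allowed bracket."""


class FitError(RuntimeError):
    """Model fitting failed (non-convergence, rank deficiency, ...)."""


class EstimationError(ValueError):
    """A requested estimate is undefined on the given data."""


def renal_failure(cohort: pd.DataFrame) -> pd.Series:
    """Derived renal-failure indicator: creatinine >2.5 mg/dL or dialysis."""
    return (cohort["creatinine_gt_2_5"].astype(bool) | cohort["dialysis"].astype(bool))


def risk_categorical(values) -> pd.Categorical:
    """Coerce category tokens into the shared ordered categorical dtype."""
    return pd.Categorical(values, categories=list(RISK_CLASSES), ordered=True)


def validate_cohort(cohort: pd.DataFrame, *, context: str = "cohort") -> None:
    """Raise :class:`SchemaError` naming every violation found.

    Checks required columns, category tokens and the LOS >= 1 floor.  Extra
    columns are tolerated (the loader warns about them separately).
    """
    problems: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"{context}: missing required columns {missing}")
    for col, levels in COHORT_COLUMNS.items():
        if levels is None:
            continue
        bad = ~cohort[col].isin(levels)
        if bad.any():
            rows = cohort.index[bad][:5].tolist()
            problems.append(
                f"column {col!r} has invalid tokens at rows {rows}"
                f" (allowed: {levels})"
            )
    los = cohort["los_days"]
    bad_los = ~(los >= 1) | (los != los.round())
    if bad_los.any():
        rows = cohort.index[bad_los][:5].tolist()
        problems.append(f"los_days must be an integer >= 1; offending rows {rows}")
    ef = cohort["ejection_fraction"]
    bad_ef = ef.notna() & ~((ef > 0) & (ef < 100))
    if bad_ef.any():
        rows = cohort.index[bad_ef][:5].tolist()
        problems.append(f"ejection_fraction outside (0, 100) at rows {rows}")
    if problems:
        raise SchemaError(f"{context}: " + "; ".join(problems))
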