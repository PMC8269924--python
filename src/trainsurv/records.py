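"""Annual trainee observation records: schema, validation and CSV round-trip.

The raw analysis input is one row per person per observed year, carrying the
training level held that year plus person-constant demographic and
socioeconomic covariates.  The calendar ``year`` labels the academic year
ending in it (year 2012 = academic year 2011/2012), and a transition between
adjacent levels is always a strict year-to-next-year step.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

#: Ordered training levels: three core years then three specialty years.
LEVELS = ["CT1", "CT2", "CT3", "ST4", "ST5", "ST6"]
LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}

#: Number of annual transitions a completer traverses (CT1->CT2 ... ST5->ST6).
N_TRANSITIONS = len(LEVELS) - 1

#: covariate name -> (category coded 1 in the hazard model, reference category).
#: The coded-1 category is the one the cohort literature reports with lower
#: completion odds; coding it 1 makes a positive hazard-model coefficient mean
#: "higher probability of not progressing".
CODING: dict[str, tuple[str, str]] = {
    "gender": ("female", "male"),
    "pmq_region": ("non-UK", "UK"),
    "ethnicity": ("BME", "White"),
    "school_type": ("state", "private"),
    "graduate_entry": ("yes", "no"),
    "disability": ("yes", "no"),
    "free_school_meals": ("yes", "no"),
    "parents_degree": ("no", "yes"),
    "imd_most_deprived": ("yes", "no"),
}

COVARIATES = list(CODING)

RECORD_COLUMNS = ["person_id", "year", "level", *COVARIATES]


class RecordValidationError(ValueError):
    """Raised when an observation-record table violates its invariants."""


def write_records(records: pd.DataFrame, path) -> None:
    """Write an observation-record table as headered CSV (missing = empty)."""
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records(path) -> pd.DataFrame:
    """Read an observation-record CSV written by :func:`write_records`."""
    df = pd.read_csv(path, dtype={c: "object" for c in RECORD_COLUMNS if c not in ("year",)})
    df["year"] = df["year"].astype(int)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"record CSV is missing columns: {missing}")
    return df[RECORD_COLUMNS]


def person_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """One row per person with their (constant) covariate values."""
    return (
        records.sort_values(["person_id", "year"])
        .groupby("person_id", as_index=False)[COVARIATES]
        .first()
    )


def validate_records(records: pd.DataFrame) -> None:
    """Check the observation-record invariants, raising on violation.

    Invariants: known columns; levels from the CT1..ST6 scale; (person, year)
    unique; covariates constant within person; per person the level sequence
    is non-decreasing in year and climbs at most one level per elapsed year.
    The error message lists offending rows by position.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise RecordValidationError(f"missing columns: {missing}")
    bad_level = ~records["level"].isin(LEVELS)
    if bad_level.any():
        rows = records.index[bad_level].tolist()[:10]
        raise RecordValidationError(f"unknown training level at rows {rows}")
    dup = records.duplicated(subset=["person_id", "year"], keep=False)
    if dup.any():
        rows = records.index[dup].tolist()[:10]
        raise RecordValidationError(f"duplicate (person_id, year) at rows {rows}")

    df = records.sort_values(["person_id", "year"])
    same_person = df["person_id"].to_numpy() == df["person_id"].shift().to_numpy()
    for cov in COVARIATES:
        vals = df[cov].to_numpy(dtype=object)
        prev = df[cov].shift().to_numpy(dtype=object)
        # NaN != NaN, so compare through pandas' null-aware equality
        differs = same_person & ~(
            (pd.isna(vals) & pd.isna(prev)) | (vals == prev)
        )
        if differs.any():
            rows = df.index[differs].tolist()[:10]
            raise RecordValidationError(
                f"covariate '{cov}' varies within person at rows {rows}"
            )

    lvl = df["level"].map(LEVEL_INDEX).to_numpy()
    yr = df["year"].to_numpy()
    dlvl = lvl - np.roll(lvl, 1)
    dyr = yr - np.roll(yr, 1)
    decreasing = same_person & (dlvl < 0)
    if decreasing.any():
        rows = df.index[decreasing].tolist()[:10]
        raise RecordValidationError(f"training level regresses at rows {rows}")
    too_fast = same_person & (dlvl > dyr)
    if too_fast.any():
        rows = df.index[too_fast].tolist()[:10]
        raise RecordValidationError(
            f"level increases faster than one per year at rows {rows}"
        )
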