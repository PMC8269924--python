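"""Build the analysis cohort and person-period dataset from annual records.

Selection keeps each person's *first* appearance at the entry level inside the
entry window (one attempt per person: later same-level reappearances are
duplicates, and a first appearance before the window disqualifies re-entry).
The person-period dataset then has one row per person per year at risk of the
event "did not progress to the next level in the minimum time"; periods after
the administrative horizon are absent (right censoring).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    COVARIATES,
    LEVEL_INDEX,
    LEVELS,
    N_TRANSITIONS,
    RecordValidationError,
    person_covariates,
    validate_records,
)

__all__ = ["CohortSpec", "select_entry_cohort", "build_person_period", "risk_table"]

PERSON_PERIOD_COLUMNS = ["person_id", "time", "event", "entry_year", *COVARIATES]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort definition: who enters, when, and how long follow-up runs.

    ``entry_window`` is inclusive; ``restrict_pmq`` optionally limits the
    cohort to one region of primary medical qualification (e.g. "UK" for the
    UK-graduate subcohorts).  ``max_time`` is the number of transitions a
    completer traverses.
    """

    entry_level: str = "CT1"
    entry_window: tuple[int, int] = (2012, 2017)
    horizon_year: int = 2018
    restrict_pmq: str | None = None
    max_time: int = N_TRANSITIONS

    def __post_init__(self):
        if self.entry_level not in LEVEL_INDEX:
            raise ValueError(f"unknown entry level '{self.entry_level}'")
        lo, hi = self.entry_window
        if lo > hi:
            raise ValueError("entry_window: start after end")
        if hi > self.horizon_year - 1:
            raise ValueError("entry_window must end before the horizon year")
        if self.max_time != len(LEVELS) - 1 - LEVEL_INDEX[self.entry_level]:
            raise ValueError("max_time must equal the number of levels above entry")


def select_entry_cohort(
    records: pd.DataFrame, spec: CohortSpec, *, validate: bool = True
) -> pd.DataFrame:
    """Select entrants: one row per person with columns person_id, entry_year.

    A person is selected iff their first appearance at the entry level falls
    inside the entry window (first-attempt rule: someone first seen at the
    entry level before the window is excluded outright, and stayer duplicates
    never create a second entry).  ``restrict_pmq`` filters on region of
    qualification.  Emits a warning, not an error, when nothing is selected.
    """
    if validate:
        validate_records(records)
    at_entry = records[records["level"] == spec.entry_level]
    first = at_entry.groupby("person_id")["year"].min()
    lo, hi = spec.entry_window
    selected = first[(first >= lo) & (first <= hi)]
    cohort = selected.rename("entry_year").reset_index()
    if spec.restrict_pmq is not None:
        covs = person_covariates(records)
        keep = covs.loc[covs["pmq_region"] == spec.restrict_pmq, "person_id"]
        cohort = cohort[cohort["person_id"].isin(keep)].reset_index(drop=True)
    if cohort.empty:
        warnings.warn("entry cohort is empty", stacklevel=2)
    return cohort.sort_values("person_id").reset_index(drop=True)


def build_person_period(
    records: pd.DataFrame, cohort: pd.DataFrame, spec: CohortSpec
) -> pd.DataFrame:
    """Expand a cohort into the person-period dataset.

    For each person and each period t = 1..max_time the expected position is
    the (entry + t)-th level in year entry_year + t.  Appearing there gives an
    at-risk row with event = 0; appearing anywhere else, or not at all, gives
    the terminal event row (event = 1) — non-progression, slower progression
    and drop-out are deliberately indistinguishable.  Periods past the horizon
    are never emitted.  A record *above* the expected level is a data error
    and raises, since levels cannot be skipped.
    """
    if cohort.empty:
        return pd.DataFrame(columns=PERSON_PERIOD_COLUMNS)
    entry_idx = LEVEL_INDEX[spec.entry_level]
    n = len(cohort)
    entry_year = cohort["entry_year"].to_numpy()

    level_num = records.assign(_lvl=records["level"].map(LEVEL_INDEX))
    lookup = level_num.set_index(["person_id", "year"])["_lvl"]

    t_grid = np.arange(1, spec.max_time + 1)
    pid_rep = np.repeat(cohort["person_id"].to_numpy(), spec.max_time)
    t_rep = np.tile(t_grid, n)
    year_rep = np.repeat(entry_year, spec.max_time) + t_rep
    idx = pd.MultiIndex.from_arrays([pid_rep, year_rep])
    observed = lookup.reindex(idx).to_numpy()  # NaN where absent

    expected = entry_idx + t_rep
    obs = observed.reshape(n, spec.max_time)
    exp_lvl = expected.reshape(n, spec.max_time)
    valid = (year_rep.reshape(n, spec.max_time)) <= spec.horizon_year

    ahead = valid & ~np.isnan(obs) & (obs > exp_lvl)
    progressed = valid & (obs == exp_lvl)
    failed = valid & ~progressed

    # first failure period (1-based); max_time+1 if none within follow-up
    any_fail = failed.any(axis=1)
    event_time = np.where(any_fail, failed.argmax(axis=1) + 1, spec.max_time + 1)
    n_valid = valid.sum(axis=1)  # follow-up periods inside the horizon

    # a record above the expected level before/at the event period is invalid
    # (sentinel past max_time + 1 so event-free completers are never flagged)
    ahead_t = np.where(ahead.any(axis=1), ahead.argmax(axis=1) + 1, spec.max_time + 2)
    bad = ahead_t <= event_time
    if bad.any():
        culprits = cohort["person_id"].to_numpy()[bad][:10].tolist()
        raise RecordValidationError(
            f"persons observed above their expected level: {culprits}"
        )

    n_rows = np.minimum(event_time, n_valid).astype(int)
    pidx = np.repeat(np.arange(n), n_rows)
    starts = np.cumsum(n_rows) - n_rows
    t_out = (np.arange(n_rows.sum()) - np.repeat(starts, n_rows)) + 1
    event = (t_out == event_time[pidx]).astype(int)

    out = pd.DataFrame(
        {
            "person_id": cohort["person_id"].to_numpy()[pidx],
            "time": t_out,
            "event": event,
            "entry_year": entry_year[pidx],
        }
    )
    covs = person_covariates(records).set_index("person_id")
    covs = covs.reindex(cohort["person_id"]).reset_index(drop=True)
    for cov in COVARIATES:
        out[cov] = covs[cov].to_numpy()[pidx]
    return out[PERSON_PERIOD_COLUMNS]


def risk_table(person_periods: pd.DataFrame, max_time: int = N_TRANSITIONS) -> pd.DataFrame:
    """Per-period counts: at-risk n_t, events d_t, censored-after c_t.

    ``censored`` counts persons whose follow-up ends event-free after period
    t with t < max_time (administrative censoring at the horizon); event-free
    persons reaching max_time are completers, not censored.  Satisfies
    n_{t+1} = n_t - d_t - c_t.
    """
    times = pd.RangeIndex(1, max_time + 1, name="time")
    if person_periods.empty:
        return pd.DataFrame(
            {"n_at_risk": 0, "events": 0, "censored": 0}, index=times
        ).reset_index()
    grp = person_periods.groupby("time")
    n_t = grp.size().reindex(times, fill_value=0)
    d_t = grp["event"].sum().reindex(times, fill_value=0)
    last = person_periods.sort_values(["person_id", "time"]).groupby("person_id").tail(1)
    cens = last[(last["event"] == 0) & (last["time"] < max_time)]
    c_t = cens.groupby("time").size().reindex(times, fill_value=0)
    out = pd.DataFrame(
        {"n_at_risk": n_t, "events": d_t, "censored": c_t}, index=times
    ).reset_index()
    return out.astype(int)
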