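import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from trainsurv.records import COVARIATES, RECORD_COLUMNS

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_records(rows, gender="male", pmq="UK"):
    """Build an observation-record frame from (person, year, level) triples."""
    df = pd.DataFrame(rows, columns=["person_id", "year", "level"])
    for cov in COVARIATES:
        df[cov] = np.nan
    df["gender"] = gender
    df["pmq_region"] = pmq
    return df[RECORD_COLUMNS]


@pytest.fixture
def ten_person_records():
    """Ten hand-written trainees exercising every selection rule.

    With entry window 2013-2016 and horizon 2018, exactly seven persons are
    selected: two stayers (selected once at first attempt), one completer,
    one immediate non-progressor, one mid-course non-progressor and two
    administratively censored persons.  Excluded: one first seen at CT2, one
    whose first CT1 year precedes the window, one whose first CT1 year
    follows it.
    """
    rows = [
        # A1: stayer, entry 2013, event at t=1
        ("A1", 2013, "CT1"), ("A1", 2014, "CT1"), ("A1", 2015, "CT2"),
        # A2: stayer, entry 2014, event at t=1
        ("A2", 2014, "CT1"), ("A2", 2015, "CT1"), ("A2", 2016, "CT1"),
        # B: first seen at CT2 -> never at entry level
        ("B", 2013, "CT2"), ("B", 2014, "CT3"),
        # C: first CT1 appearance (2012) precedes the window -> excluded
        ("C", 2012, "CT1"), ("C", 2013, "CT1"),
        # D: first CT1 appearance (2017) follows the window -> excluded
        ("D", 2017, "CT1"), ("D", 2018, "CT2"),
        # E: completer, entry 2013
        ("E", 2013, "CT1"), ("E", 2014, "CT2"), ("E", 2015, "CT3"),
        ("E", 2016, "ST4"), ("E", 2017, "ST5"), ("E", 2018, "ST6"),
        # F: entry 2016, progresses twice, censored after t=2
        ("F", 2016, "CT1"), ("F", 2017, "CT2"), ("F", 2018, "CT3"),
        # G: entry 2016, vanishes -> event at t=1
        ("G", 2016, "CT1"),
        # H: entry 2013, event at t=3 (absent in 2016)
        ("H", 2013, "CT1"), ("H", 2014, "CT2"), ("H", 2015, "CT3"),
        # I: entry 2015, three progressions, censored after t=3
        ("I", 2015, "CT1"), ("I", 2016, "CT2"), ("I", 2017, "CT3"),
        ("I", 2018, "ST4"),
    ]
    return make_records(rows)


#: Hand-enumerated expectations for the ten-person fixture.
TEN_PERSON_SELECTED = {"A1": 2013, "A2": 2014, "E": 2013, "F": 2016,
                       "G": 2016, "H": 2013, "I": 2015}
TEN_PERSON_RISK = pd.DataFrame(
    {
        "time": [1, 2, 3, 4, 5],
        "n_at_risk": [7, 4, 3, 1, 1],
        "events": [3, 0, 1, 0, 0],
        "censored": [0, 1, 1, 0, 0],
    }
)
#: KM by hand: S1 = 4/7; t=3 factor 2/3 -> S3..S5 = 8/21.
TEN_PERSON_KM = np.array([4 / 7, 4 / 7, 8 / 21, 8 / 21, 8 / 21])
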