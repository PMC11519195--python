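"""Published descriptive counts for Seoul, 2014-2019, as test/acceptance fixtures.

The underlying registries (emergency-department visits, cause-of-death
records, station weather) are restricted-access, but the published
descriptive composition of the Seoul 2014-2019 study population is public:
35,518 non-fatal intentional self-harm (ISH) visits and 13,416 suicide
deaths, with sex, age-band and mechanism margins.  This module expands
those printed counts into synthetic record-level tables whose margins
reproduce them exactly, so the descriptive tabulation and the
inclusion/exclusion arithmetic can be exercised end to end.  The joint
distribution of mechanism within sex/age cells is NOT published; records
pair the two margins arbitrarily, which leaves every tabulated margin
exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ISH_SEX_AGE_COUNTS",
    "ISH_MECHANISM_COUNTS",
    "DEATH_SEX_AGE_COUNTS",
    "DEATH_MECHANISM_COUNTS",
    "ER_TOTAL_WITH_FATAL",
    "ER_DEATH_COUNT",
    "POSTHOSP_DEATH_EXCLUDED",
    "descriptive_records",
    "intake_records",
]

# sex x age-band counts of the two outcome series
ISH_SEX_AGE_COUNTS: dict[tuple[str, str], int] = {
    ("female", "0-34"): 9120,
    ("female", "35-64"): 9790,
    ("female", "65+"): 2182,
    ("male", "0-34"): 5121,
    ("male", "35-64"): 7097,
    ("male", "65+"): 2208,
}
DEATH_SEX_AGE_COUNTS: dict[tuple[str, str], int] = {
    ("female", "0-34"): 1140,
    ("female", "35-64"): 2014,
    ("female", "65+"): 1051,
    ("male", "0-34"): 1575,
    ("male", "35-64"): 5326,
    ("male", "65+"): 2310,
}

ISH_MECHANISM_COUNTS: dict[str, int] = {
    "poisoning": 18775,
    "drowning": 690,
    "hanging": 1358,
    "jumping": 726,
    "sharp objects": 9791,
    "others": 4178,
}
DEATH_MECHANISM_COUNTS: dict[str, int] = {
    "poisoning": 2577,
    "drowning": 876,
    "hanging": 7117,
    "jumping": 2483,
    "sharp objects": 151,
    "others": 212,
}

#: all ISH visits including emergency-room deaths (after excluding the
#: post-hospitalization death group)
ER_TOTAL_WITH_FATAL = 36936
#: ISH visits with a death level in the emergency treatment result
ER_DEATH_COUNT = 1418
#: visits excluded up front because the post-hospitalization result was death
POSTHOSP_DEATH_EXCLUDED = 410

_BAND_AGE = {"0-34": 25, "35-64": 50, "65+": 72}
_MECH_ICD10 = {
    "poisoning": "X60",
    "drowning": "X71",
    "hanging": "X70",
    "jumping": "X80",
    "sharp objects": "X78",
    "others": "X83",
}
_WINDOW = pd.date_range("2014-01-01", "2019-12-31", freq="D")


def _expand(sex_age: dict[tuple[str, str], int], mechanisms: dict[str, int]) -> pd.DataFrame:
    total = sum(sex_age.values())
    assert total == sum(mechanisms.values())
    sex = np.repeat([s for s, _ in sex_age], list(sex_age.values()))
    age = np.repeat([_BAND_AGE[b] for _, b in sex_age], list(sex_age.values()))
    mech = np.repeat(list(mechanisms), list(mechanisms.values()))
    dates = _WINDOW[np.arange(total) % len(_WINDOW)]
    return pd.DataFrame(
        {"record_id": np.arange(total), "event_date": dates, "sex": sex, "age": age, "mechanism": mech}
    )


def descriptive_records() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Record-level (ISH, deaths) tables reproducing the published margins."""
    ish = _expand(ISH_SEX_AGE_COUNTS, ISH_MECHANISM_COUNTS)
    ish["intentionality"] = "intentional self-harm"
    ish["er_result"] = "discharge"
    ish["posthosp_result"] = "normal discharge"

    dth = _expand(DEATH_SEX_AGE_COUNTS, DEATH_MECHANISM_COUNTS)
    dth = dth.rename(columns={"event_date": "date"})
    dth["icd10"] = dth.pop("mechanism").map(_MECH_ICD10)
    return ish, dth


def intake_records() -> pd.DataFrame:
    """The raw emergency intake behind the inclusion/exclusion flow.

    36,936 ISH visits of which 1,418 died in the emergency room, plus the
    410 visits excluded because the post-hospitalization result was death:
    37,346 rows in total.  Filtering with ``select_ish`` reproduces the
    published analysis-set sizes (35,518 non-fatal; 36,936 with fatal).
    """
    n_clean = ER_TOTAL_WITH_FATAL - ER_DEATH_COUNT
    er = np.concatenate(
        [
            np.repeat("discharge", n_clean),
            np.repeat("death", ER_DEATH_COUNT),
            np.repeat("admission", POSTHOSP_DEATH_EXCLUDED),
        ]
    )
    posthosp = np.concatenate(
        [
            np.repeat("normal discharge", n_clean),
            np.repeat("not applicable", ER_DEATH_COUNT),
            np.repeat("death", POSTHOSP_DEATH_EXCLUDED),
        ]
    )
    n = er.size
    return pd.DataFrame(
        {
            "record_id": np.arange(n),
            "event_date": _WINDOW[np.arange(n) % len(_WINDOW)],
            "sex": np.where(np.arange(n) % 2 == 0, "female", "male"),
            "age": 40,
            "intentionality": "intentional self-harm",
            "mechanism": "poisoning",
            "er_result": er,
            "posthosp_result": posthosp,
        }
    )
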