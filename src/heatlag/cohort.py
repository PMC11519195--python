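"""Cohort construction: inclusion/exclusion filters, subgroups, aggregation.

The analysis distinguishes two outcomes drawn from two registries:

* **non-fatal intentional self-harm (ISH)** — emergency-department visits
  whose intentionality is recorded as intentional self-harm or suicide,
  excluding every record with a death level in either the emergency
  treatment result or the post-hospitalization result;
* **suicide deaths** — cause-of-death registry records with an ICD-10 code
  in the intentional self-harm range X60-X84.

A robustness variant (``include_fatal=True``) keeps the emergency-room
deaths in the ISH series; records whose post-hospitalization result is a
death are excluded from every analysis set.  Subgroups cross sex with the
age bands 0-34, 35-64 and >=65.
"""

from __future__ import annotations

import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Subgroup",
    "select_ish",
    "select_suicide_deaths",
    "assign_age_band",
    "assign_subgroup",
    "aggregate_daily",
    "tabulate_descriptives",
    "mechanism_from_icd10",
]

logger = logging.getLogger(__name__)

ISH_INTENTS = frozenset({"intentional self-harm", "suicide"})
KNOWN_INTENTS = ISH_INTENTS | {"unintentional", "violence", "assault", "undetermined", "other"}
DEATH_LEVEL = "death"
AGE_BANDS = ("0-34", "35-64", "65+")


class Subgroup(NamedTuple):
    """Sex x age-band cell; 'all' marginalizes a dimension."""

    sex: str = "all"
    age_band: str = "all"

    @property
    def label(self) -> str:
        return f"{self.sex}/{self.age_band}"


def assign_age_band(age) -> pd.Series | str:
    """Band assignment: 0-34 (age <= 34), 35-64, >=65."""
    scalar = np.isscalar(age)
    a = pd.Series(np.atleast_1d(age))
    if (a < 0).any():
        raise ValueError("age must be >= 0")
    band = pd.cut(a, bins=[-0.5, 34.5, 64.5, np.inf], labels=AGE_BANDS).astype(str)
    return band.iloc[0] if scalar else band


def assign_subgroup(record: pd.Series) -> Subgroup:
    """Subgroup cell of one record."""
    return Subgroup(sex=str(record["sex"]), age_band=assign_age_band(int(record["age"])))


def _drop_missing_demographics(records: pd.DataFrame) -> pd.DataFrame:
    missing = records["sex"].isna() | records["age"].isna()
    if missing.any():
        logger.warning("excluding %d records with missing sex/age", int(missing.sum()))
    return records[~missing]


def select_ish(records: pd.DataFrame, include_fatal: bool = False) -> pd.DataFrame:
    """Select intentional self-harm visits from the emergency registry.

    Keeps intentionality levels 'intentional self-harm' and 'suicide'
    (pooled).  Records whose post-hospitalization result is a death are
    always excluded.  Emergency-room deaths are excluded unless
    ``include_fatal`` is True (the robustness variant that keeps fatal
    visits in the series).  Returns a new DataFrame; the input is untouched.
    """
    for col in ("er_result", "posthosp_result"):
        if col not in records.columns:
            raise ValueError(f"records are missing the required result field {col!r}")
    intent = records["intentionality"].astype(str)
    unknown = ~intent.isin(KNOWN_INTENTS)
    if unknown.any():
        warnings.warn(
            f"excluding {int(unknown.sum())} records with unknown intentionality levels "
            f"{sorted(intent[unknown].unique())}"
        )
    out = records[intent.isin(ISH_INTENTS)]
    out = _drop_missing_demographics(out)
    out = out[out["posthosp_result"] != DEATH_LEVEL]
    if not include_fatal:
        out = out[out["er_result"] != DEATH_LEVEL]
    return out.copy()


def select_suicide_deaths(records: pd.DataFrame) -> pd.DataFrame:
    """Select suicide deaths by ICD-10 cause code in X60-X84.

    Codes are upper-cased and truncated to the three-character category, so
    subcodes (X70.9, x709) match their category.  Malformed codes are
    excluded with a warning.
    """
    if records.empty:
        return records.copy()
    codes = records["icd10"].astype(str).str.strip().str.upper()
    cat = codes.str.replace(".", "", regex=False).str[:3]
    wellformed = cat.str.match(r"^[A-Z][0-9]{2}$").fillna(False)
    if (~wellformed).any():
        warnings.warn(f"excluding {int((~wellformed).sum())} records with malformed ICD-10 codes")
    num = pd.to_numeric(cat.str[1:], errors="coerce")
    keep = wellformed & (cat.str[0] == "X") & (num >= 60) & (num <= 84)
    return records[keep].copy()


def mechanism_from_icd10(code: str) -> str:
    """Standard mechanism grouping of the X60-X84 cause categories."""
    cat = str(code).strip().upper().replace(".", "")[:3]
    n = int(cat[1:])
    if 60 <= n <= 69:
        return "poisoning"
    return {70: "hanging", 71: "drowning", 78: "sharp objects", 80: "jumping"}.get(n, "others")


def aggregate_daily(
    records: pd.DataFrame,
    calendar: pd.DatetimeIndex,
    subgroup: Subgroup = Subgroup(),
    date_col: str | None = None,
) -> pd.Series:
    """Daily event counts for one subgroup, with explicit zero days.

    The sum over days equals the number of subgroup records; a record dated
    outside the calendar raises.
    """
    calendar = pd.DatetimeIndex(calendar)
    date_col = date_col or ("event_date" if "event_date" in records.columns else "date")
    df = records
    if subgroup.sex != "all":
        df = df[df["sex"] == subgroup.sex]
    if subgroup.age_band != "all":
        df = df[np.asarray(assign_age_band(df["age"].to_numpy())) == subgroup.age_band]
    dates = pd.DatetimeIndex(pd.to_datetime(df[date_col])).normalize()
    outside = ~dates.isin(calendar)
    if outside.any():
        raise ValueError(
            f"{int(outside.sum())} records dated outside the calendar, e.g. {dates[outside][0].date()}"
        )
    counts = pd.Series(dates).value_counts().reindex(calendar, fill_value=0).astype(int)
    counts.name = "count"
    return counts


def _pct(n: int, total: int) -> float:
    """Share in percent, rounded half-up to one decimal."""
    if total == 0:
        return float("nan")
    share = Decimal(n) * 100 / Decimal(total)
    return float(share.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tabulate_descriptives(records_ish: pd.DataFrame, records_death: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by sex, age band, sex x age, and mechanism.

    Percentages are computed against each outcome's own total and rounded
    half-up to one decimal.  Death mechanisms derive from the ICD-10
    category when no mechanism column is present.
    """
    if records_ish.empty or records_death.empty:
        raise ValueError("both record sets must be non-empty")

    def prepare(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["age_band"] = np.asarray(assign_age_band(df["age"].to_numpy()))
        if "mechanism" not in df.columns:
            df["mechanism"] = df["icd10"].map(mechanism_from_icd10)
        return df

    ish = prepare(records_ish)
    dth = prepare(records_death)
    n_ish, n_dth = len(ish), len(dth)

    rows: list[dict] = [
        {"variable": "total", "level": "all", "ish_n": n_ish, "death_n": n_dth}
    ]

    def section(variable: str, key) -> None:
        ish_counts = ish.groupby(key(ish)).size()
        dth_counts = dth.groupby(key(dth)).size()
        for level in sorted(set(ish_counts.index) | set(dth_counts.index)):
            rows.append(
                {
                    "variable": variable,
                    "level": level if isinstance(level, str) else "/".join(level),
                    "ish_n": int(ish_counts.get(level, 0)),
                    "death_n": int(dth_counts.get(level, 0)),
                }
            )

    section("sex", lambda d: d["sex"])
    section("age", lambda d: d["age_band"])
    section("sex/age", lambda d: [d["sex"], d["age_band"]])
    section("mechanism", lambda d: d["mechanism"])

    table = pd.DataFrame(rows)
    table["ish_pct"] = [_pct(n, n_ish) for n in table["ish_n"]]
    table["death_pct"] = [_pct(n, n_dth) for n in table["death_n"]]
    return table[["variable", "level", "ish_n", "ish_pct", "death_n", "death_pct"]]
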