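"""Baseline characterisation of the cohort (external-validation table).

Produces the counts-and-percentages table used to compare the cohort with
other samples of people who use illicit opioids: age at index, sex, region,
smoking status (most recent record, with current smoking expected to
dominate), deprivation quintile, and lifetime history flags (homelessness,
prison, alcohol dependence), plus the calendar trend in mean age at entry.

Smoking and flag codelists are user-supplied tables, not part of the
phenotype codelist: smoking maps each code to CURRENT/EX/NEVER, flags are
plain code sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ENGLAND_REGIONS, imputed_birth_date
from .persontime import DAYS_PER_YEAR

AGE_GROUPS: tuple[tuple[int, int], ...] = ((18, 29), (30, 39), (40, 49), (50, 64))
SMOKING_LEVELS = ("CURRENT", "EX", "NEVER", "NO_RECORDS")
_SMOKING_PRIORITY = {"CURRENT": 3, "EX": 2, "NEVER": 1}


def smoking_status_all(
    events: pd.DataFrame,
    smoking_codelist: pd.DataFrame,
    patient_ids: pd.Series,
    before: pd.Series | None = None,
) -> pd.Series:
    """Smoking status per patient: the status of the latest-dated record.

    ``smoking_codelist`` has columns ``code_id``, ``terminology``, ``status``
    (CURRENT/EX/NEVER).  Same-day ties resolve CURRENT > EX > NEVER.
    Patients with no smoking record get NO_RECORDS.  ``before``, if given,
    is a per-patient cut-off date (records on/after it are ignored),
    supporting a "most recent before index" variant; the default uses every
    record.
    """
    ev = events.merge(
        smoking_codelist[["code_id", "terminology", "status"]],
        on=["code_id", "terminology"],
    )
    ev = ev[ev["patient_id"].isin(patient_ids)]
    if before is not None:
        cutoff = pd.DataFrame({"patient_id": patient_ids, "cutoff": before.to_numpy()})
        ev = ev.merge(cutoff, on="patient_id")
        ev = ev[pd.to_datetime(ev["date"]) < ev["cutoff"]]
    ev = ev.assign(
        date=pd.to_datetime(ev["date"]),
        rank=ev["status"].map(_SMOKING_PRIORITY),
    ).sort_values(["date", "rank"], kind="stable")
    latest = ev.groupby("patient_id")["status"].last()
    return (
        pd.Series(patient_ids.to_numpy(), name="patient_id")
        .map(latest)
        .fillna("NO_RECORDS")
        .set_axis(patient_ids.index)
    )


def smoking_status(events: pd.DataFrame, smoking_codelist: pd.DataFrame) -> str:
    """Status for a single patient's events (NO_RECORDS if none)."""
    ids = pd.Series(events["patient_id"].unique())
    if len(ids) == 0:
        return "NO_RECORDS"
    if len(ids) > 1:
        raise ValueError("events span multiple patients")
    return smoking_status_all(events, smoking_codelist, ids).iloc[0]


def history_flag_all(
    events: pd.DataFrame, flag_codelist: pd.DataFrame, patient_ids: pd.Series
) -> pd.Series:
    """True per patient iff ≥1 matching record at any time (lifetime flag)."""
    ev = events.merge(
        flag_codelist[["code_id", "terminology"]], on=["code_id", "terminology"]
    )
    flagged = set(ev["patient_id"].unique())
    return pd.Series(
        [pid in flagged for pid in patient_ids], index=patient_ids.index, dtype=bool
    )


def history_flag(events: pd.DataFrame, flag_codelist: pd.DataFrame) -> bool:
    """Lifetime history flag for a single patient's events."""
    return bool(
        len(events.merge(flag_codelist[["code_id", "terminology"]], on=["code_id", "terminology"]))
    )


def _block(values: pd.Series, levels: list) -> pd.DataFrame:
    counts = values.value_counts()
    n = len(values)
    rows = [
        {
            "level": str(level),
            "count": int(counts.get(level, 0)),
            "pct": round(100 * counts.get(level, 0) / n, 1) if n else np.nan,
        }
        for level in levels
    ]
    return pd.DataFrame(rows)


@dataclass
class BaselineTable:
    """Counts and percentages per categorical block, plus medians/IQRs.

    Each block is a DataFrame (level, count, pct) partitioning the cohort.
    """

    cohort_size: int
    blocks: dict[str, pd.DataFrame] = field(default_factory=dict)
    age_median: float = np.nan
    age_q1: float = np.nan
    age_q3: float = np.nan
    followup_median: float = np.nan
    followup_q1: float = np.nan
    followup_q3: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        parts = [
            b.assign(variable=name)[["variable", "level", "count", "pct"]]
            for name, b in self.blocks.items()
        ]
        out = pd.concat(parts, ignore_index=True)
        extra = pd.DataFrame(
            {
                "variable": ["age_at_index", "followup_years"],
                "level": ["median (IQR)"] * 2,
                "count": [np.nan, np.nan],
                "pct": [np.nan, np.nan],
            }
        )
        extra["summary"] = [
            f"{self.age_median:.1f} ({self.age_q1:.1f}-{self.age_q3:.1f})",
            f"{self.followup_median:.1f} ({self.followup_q1:.1f}-{self.followup_q3:.1f})",
        ]
        return pd.concat([out, extra], ignore_index=True)


def baseline_table(
    members: pd.DataFrame,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    smoking_codelist: pd.DataFrame | None = None,
    flag_codelists: dict[str, pd.DataFrame] | None = None,
    regions: tuple[str, ...] = ENGLAND_REGIONS,
) -> BaselineTable:
    """Build the baseline characteristics table for a cohort.

    Age at index is the exact (fractional) age at entry against the mid-year
    imputed birth date; age groups use completed years.  Medians and
    quartiles use linear interpolation.  Every categorical block partitions
    the cohort (counts sum to cohort size).
    """
    m = members.merge(
        patients[["patient_id", "region", "imd_quintile"]], on="patient_id", how="left"
    )
    n = len(m)
    birth = imputed_birth_date(m["year_of_birth"])
    age_exact = (m["entry"].to_numpy() - birth.to_numpy()) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    followup = (m["exit"].to_numpy() - m["entry"].to_numpy()) / np.timedelta64(1, "D") / DAYS_PER_YEAR

    age_labels = [f"{lo}-{hi}" for lo, hi in AGE_GROUPS]
    age_group = pd.cut(
        m["age_at_entry"],
        bins=[lo for lo, _ in AGE_GROUPS] + [AGE_GROUPS[-1][1] + 1],
        labels=age_labels,
        right=False,
    ).astype(str)

    table = BaselineTable(cohort_size=n)
    table.blocks["age_group"] = _block(age_group, age_labels)
    table.blocks["sex"] = _block(m["sex"], ["M", "F"])
    table.blocks["region"] = _block(
        m["region"].fillna("Missing"), list(regions) + ["Missing"]
    )
    imd = m["imd_quintile"].map(
        lambda q: "Missing" if pd.isna(q) else str(int(q))
    )
    table.blocks["imd_quintile"] = _block(imd, ["1", "2", "3", "4", "5", "Missing"])

    if smoking_codelist is not None:
        status = smoking_status_all(events, smoking_codelist, m["patient_id"])
        table.blocks["smoking"] = _block(status, list(SMOKING_LEVELS))
    for name, flag_list in (flag_codelists or {}).items():
        flags = history_flag_all(events, flag_list, m["patient_id"])
        table.blocks[name] = _block(
            flags.map({True: "Yes", False: "No"}), ["Yes", "No"]
        )

    if n:
        table.age_q1, table.age_median, table.age_q3 = np.percentile(age_exact, [25, 50, 75])
        table.followup_q1, table.followup_median, table.followup_q3 = np.percentile(
            followup, [25, 50, 75]
        )
    return table


def entry_age_trend(members: pd.DataFrame) -> pd.DataFrame:
    """Mean age at entry by calendar year of entry.

    Returns one row per entry year (``year``, ``mean_age``, ``n``); a rising
    series reflects the ageing of the population of people who use illicit
    opioids.
    """
    if len(members) == 0:
        raise ValueError("no members")
    birth = imputed_birth_date(members["year_of_birth"])
    age_exact = (
        (members["entry"].to_numpy() - birth.to_numpy())
        / np.timedelta64(1, "D")
        / DAYS_PER_YEAR
    )
    df = pd.DataFrame({"year": members["entry"].dt.year, "age": age_exact})
    out = df.groupby("year", as_index=False).agg(mean_age=("age", "mean"), n=("age", "size"))
    return out.sort_values("year").reset_index(drop=True)


def trend_slope(trend: pd.DataFrame) -> float:
    """Least-squares slope of mean entry age on entry year (years per year)."""
    if len(trend) < 2:
        raise ValueError("need at least two entry years to fit a trend")
    return float(np.polyfit(trend["year"], trend["mean_age"], 1, w=np.sqrt(trend["n"]))[0])
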