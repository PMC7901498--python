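"""Cohort assembly: entry/exit dates, eligibility rules, exclusion tally.

A patient enters the cohort at the latest of the study start, the first date
with good-quality data, and the first code indicating illicit opioid use;
they exit at the earliest of the end of data collection and death.  Entry
must fall at age 18-64, in a configured region set, and leave positive
follow-up after capping exit at the study end.  Exclusions are tallied in a
fixed order (no code → region → no follow-up → age) so the counts mirror a
recruitment flow chart.

The registry supplies year of birth only; ages are computed against an
imputed birth date of 1 July of the birth year (mid-year imputation
minimises the maximum error).  Follow-up is the half-open interval
[entry, exit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codelist import Category, Codelist, Terminology

logger = logging.getLogger(__name__)

#: The nine English regions used by the regional breakdown.
ENGLAND_REGIONS: tuple[str, ...] = (
    "East Midlands",
    "East of England",
    "London",
    "North East",
    "North West",
    "South East",
    "South West",
    "West Midlands",
    "Yorkshire & The Humber",
)

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "year_of_birth",
    "region",
    "imd_quintile",
    "data_start",
    "data_end",
    "death_date",
]

MEMBER_COLUMNS = [
    "patient_id",
    "sex",
    "year_of_birth",
    "entry",
    "exit",
    "index_code_date",
    "age_at_entry",
    "died",
    "death_date",
]


def imputed_birth_date(year_of_birth) -> pd.Series | pd.Timestamp:
    """1 July of the birth year (scalar or Series)."""
    if np.isscalar(year_of_birth):
        return pd.Timestamp(int(year_of_birth), 7, 1)
    yob = pd.Series(year_of_birth).astype(int)
    return pd.to_datetime(
        {"year": yob, "month": 7, "day": 1}
    )


def age_in_completed_years(birth, on) -> pd.Series | int:
    """Age in completed years on a given date.

    Vectorised when given Series; exact calendar arithmetic (a birthday on
    the date itself counts as completed).
    """
    scalar = isinstance(birth, pd.Timestamp) and isinstance(on, pd.Timestamp)
    b = pd.DatetimeIndex([birth] if scalar else pd.Series(birth))
    d = pd.DatetimeIndex([on] if scalar else pd.Series(on))
    before_birthday = (d.month < b.month) | ((d.month == b.month) & (d.day < b.day))
    age = d.year - b.year - before_birthday.astype(int)
    if scalar:
        return int(age[0])
    return pd.Series(np.asarray(age), index=pd.Series(on).index)


@dataclass(frozen=True)
class CohortConfig:
    """Rules applied when assembling the cohort."""

    study_start: pd.Timestamp = pd.Timestamp("1997-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2018-12-31")
    regions: tuple[str, ...] | None = ENGLAND_REGIONS
    include_probable: bool = False
    #: when True, the index code must fall on/after the patient's data_start
    #: (historical codes recorded pre-registration are otherwise accepted)
    require_code_in_registration: bool = False
    min_age: int = 18
    max_age: int = 64  # inclusive: entry at 18..64 completed years

    def __post_init__(self) -> None:
        if pd.Timestamp(self.study_end) < pd.Timestamp(self.study_start):
            raise ValueError("study_end must be >= study_start")


@dataclass
class ExclusionTally:
    """Counts removed at each eligibility step, in application order."""

    no_code: int = 0
    region: int = 0
    no_follow_up: int = 0
    age: int = 0
    final: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": ["no_code", "region", "no_follow_up", "age", "final_cohort"],
                "count": [self.no_code, self.region, self.no_follow_up, self.age, self.final],
            }
        )


def compute_entry(
    data_start: pd.Timestamp, first_code_date: pd.Timestamp, study_start: pd.Timestamp
) -> pd.Timestamp:
    """Entry = latest of study start, data start, and first phenotype code."""
    return max(pd.Timestamp(study_start), pd.Timestamp(data_start), pd.Timestamp(first_code_date))


def compute_exit(data_end: pd.Timestamp, death_date: pd.Timestamp | None = None) -> pd.Timestamp:
    """Exit = earliest of end of data collection and death (if recorded)."""
    data_end = pd.Timestamp(data_end)
    if death_date is None or pd.isna(death_date):
        return data_end
    return min(data_end, pd.Timestamp(death_date))


def _codelist_frame(codelist: Codelist, include_probable: bool) -> pd.DataFrame:
    cats = codelist.matching_categories(include_probable)
    return pd.DataFrame(
        [
            {"terminology": e.terminology.value, "code_id": e.code_id, "category": e.category.value}
            for e in codelist
            if e.category in cats
        ],
        columns=["terminology", "code_id", "category"],
    )


def match_all_codes(
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelist: Codelist,
    include_probable: bool = False,
) -> pd.DataFrame:
    """Dated phenotype-code matches for every patient (vectorised).

    Clinical events (``patient_id, date, code_id, terminology``) and
    prescriptions (``patient_id, date, product_code``; matched against
    PRODUCT-terminology entries) are pooled.  Returns columns
    ``patient_id, date, category`` sorted by patient then date.  Events with
    a terminology absent from the vocabulary are skipped with a logged
    warning count.
    """
    ev = events[["patient_id", "date", "code_id", "terminology"]].copy()
    known_terms = {t.value for t in Terminology}
    unknown = ~ev["terminology"].isin(known_terms)
    if unknown.any():
        logger.warning("skipped %d events with unknown terminology", int(unknown.sum()))
        ev = ev[~unknown]
    rx = prescriptions.rename(columns={"product_code": "code_id"})[
        ["patient_id", "date", "code_id"]
    ].copy()
    rx["terminology"] = Terminology.PRODUCT.value
    pooled = pd.concat([ev, rx], ignore_index=True)
    pooled["date"] = pd.to_datetime(pooled["date"])
    pooled["code_id"] = pooled["code_id"].astype(str)
    matched = pooled.merge(
        _codelist_frame(codelist, include_probable), on=["terminology", "code_id"]
    )
    return matched[["patient_id", "date", "category"]].sort_values(
        ["patient_id", "date"], kind="stable"
    ).reset_index(drop=True)


def build_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelist: Codelist,
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Assemble the phenotype-positive cohort.

    Returns the member table (``MEMBER_COLUMNS``) and the exclusion tally.
    Members satisfy: at least one phenotype-code match, region in the
    configured set, positive follow-up within the study window, and entry at
    age ``min_age``..``max_age`` completed years.

    Duplicate patient ids in the registry are a hard error.
    """
    config = config or CohortConfig()
    pats = patients.copy()
    if pats["patient_id"].duplicated().any():
        dups = pats.loc[pats["patient_id"].duplicated(), "patient_id"].unique()
        raise ValueError(f"duplicate patient ids in registry: {list(dups[:5])}")
    for col in ("data_start", "data_end", "death_date"):
        pats[col] = pd.to_datetime(pats[col], errors="raise")

    matches = match_all_codes(events, prescriptions, codelist, config.include_probable)
    if config.require_code_in_registration:
        matches = matches.merge(pats[["patient_id", "data_start"]], on="patient_id")
        matches = matches[matches["date"] >= matches["data_start"]]
    first_code = matches.groupby("patient_id", sort=False)["date"].min()

    tally = ExclusionTally()
    df = pats.merge(first_code.rename("index_code_date"), on="patient_id", how="left")
    positive = df["index_code_date"].notna()
    tally.no_code = int((~positive).sum())
    df = df[positive]

    if config.regions is not None:
        in_region = df["region"].isin(config.regions)
        tally.region = int((~in_region).sum())
        df = df[in_region]

    study_start = pd.Timestamp(config.study_start)
    study_end = pd.Timestamp(config.study_end)
    entry = df[["data_start", "index_code_date"]].max(axis=1).clip(lower=study_start)
    exit_raw = df["data_end"].where(
        df["death_date"].isna(), np.minimum(df["data_end"], df["death_date"])
    )
    exit_ = exit_raw.clip(upper=study_end)
    has_followup = entry < exit_
    tally.no_follow_up = int((~has_followup).sum())
    df, entry, exit_ = df[has_followup], entry[has_followup], exit_[has_followup]

    birth = imputed_birth_date(df["year_of_birth"])
    birth.index = df.index
    age_at_entry = age_in_completed_years(birth, entry)
    age_ok = (age_at_entry >= config.min_age) & (age_at_entry <= config.max_age)
    tally.age = int((~age_ok).sum())
    df, entry, exit_, age_at_entry = (
        df[age_ok],
        entry[age_ok],
        exit_[age_ok],
        age_at_entry[age_ok],
    )

    members = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "sex": df["sex"],
            "year_of_birth": df["year_of_birth"].astype(int),
            "entry": entry,
            "exit": exit_,
            "index_code_date": df["index_code_date"],
            "age_at_entry": age_at_entry.astype(int),
            "died": df["death_date"].notna() & (df["death_date"] <= exit_),
            "death_date": df["death_date"],
        }
    ).reset_index(drop=True)
    tally.final = len(members)
    return members, tally


def overlap_summary(
    members: pd.DataFrame,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelist: Codelist,
    include_probable: bool = False,
) -> dict[str, int]:
    """Partition members by evidence type: OAT prescription only, clinical
    code only, or both.  The three counts sum to the cohort size."""
    matches = match_all_codes(events, prescriptions, codelist, include_probable)
    matches = matches[matches["patient_id"].isin(members["patient_id"])]
    kinds = matches.assign(
        is_product=matches["category"] == Category.OAT_PRODUCT.value
    ).groupby("patient_id")["is_product"].agg(["any", "all"])
    has_product = kinds["any"]
    only_product = kinds["all"]
    both = int((has_product & ~only_product).sum())
    product_only = int(only_product.sum())
    clinical_only = int((~has_product).sum())
    counts = {"product_only": product_only, "clinical_only": clinical_only, "both": both}
    assert sum(counts.values()) == len(members)
    return counts
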