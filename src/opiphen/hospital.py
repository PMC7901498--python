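"""Internal validation against hospital admissions with opioid diagnoses.

Hospital admissions carrying ICD-10 F11 ("mental and behavioural disorders
due to use of opioids") in any diagnostic position give an independent view
of the same condition.  The sensitivity check reports, among patients with
at least one such admission, the fraction who also hold a primary-care
phenotype code, broken down by timing: code before the first admission,
within 30 days after it (day 0 counts as after), or later — later records
may simply transcribe hospital discharge summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codelist import Codelist
from .cohort import match_all_codes

_ICD10_SHAPE = re.compile(r"^[A-Z][0-9][0-9A-Z]*(\.[0-9A-Z]+)?$")

TIMING_LEVELS = ("BEFORE", "WITHIN_30_AFTER", "LATER")


@dataclass(frozen=True)
class ValidationSummary:
    """Sensitivity of the primary-care phenotype among hospital cases."""

    n_hospital_cases: int
    fraction_with_primary_care_code: float  # NaN when no hospital cases
    fraction_before: float
    fraction_within_30_after: float
    fraction_later: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_hospital_cases": self.n_hospital_cases,
                    "fraction_with_primary_care_code": self.fraction_with_primary_care_code,
                    "fraction_before": self.fraction_before,
                    "fraction_within_30_after": self.fraction_within_30_after,
                    "fraction_later": self.fraction_later,
                }
            ]
        )


def _codes_match_prefix(codes: str | list[str], prefix: str) -> bool:
    if isinstance(codes, str):
        codes = codes.split(";")
    # prefix semantics: F11, F11.1, F110 all match "F11"
    return any(c.strip().upper().startswith(prefix.upper()) for c in codes if c.strip())


def first_f11_admission(
    admissions: pd.DataFrame, code_prefix: str = "F11"
) -> pd.Timestamp | None:
    """Earliest admission date (one patient) with a qualifying diagnosis.

    ``admissions`` has columns ``admission_date`` and ``diagnosis_codes``
    (semicolon-joined ICD-10 codes, any diagnostic position).  Returns None
    when no admission qualifies.
    """
    hits = admissions[
        admissions["diagnosis_codes"]
        .map(lambda c: _codes_match_prefix(c, code_prefix))
        .astype(bool)
    ]
    if len(hits) == 0:
        return None
    return pd.to_datetime(hits["admission_date"]).min()


def first_qualifying_admissions(
    admissions: pd.DataFrame, code_prefix: str = "F11"
) -> pd.Series:
    """Earliest qualifying admission date per patient (vectorised)."""
    qual = admissions[
        admissions["diagnosis_codes"]
        .map(lambda c: _codes_match_prefix(c, code_prefix))
        .astype(bool)
    ].copy()
    qual["admission_date"] = pd.to_datetime(qual["admission_date"])
    return qual.groupby("patient_id")["admission_date"].min()


def classify_timing(
    first_code_date: pd.Timestamp, first_admission_date: pd.Timestamp
) -> str:
    """BEFORE / WITHIN_30_AFTER / LATER relative to the first admission.

    The post-admission window is [admission, admission + 30 days] inclusive;
    a same-day code is day 0 of that window.
    """
    code = pd.Timestamp(first_code_date)
    adm = pd.Timestamp(first_admission_date)
    if code < adm:
        return "BEFORE"
    if code <= adm + pd.Timedelta(days=30):
        return "WITHIN_30_AFTER"
    return "LATER"


def validation_summary(
    patients: pd.DataFrame,
    admissions: pd.DataFrame,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelist: Codelist,
    include_probable: bool = False,
    code_prefix: str = "F11",
) -> ValidationSummary:
    """Phenotype sensitivity among patients hospitalised with opioid disorder.

    The denominator is registry patients with ≥1 qualifying admission; the
    numerator windows (before / within 30 days after / later than the first
    admission) partition those who also hold a phenotype code, so the three
    timing fractions sum to the overall fraction.  With zero hospital cases
    the fractions are reported as NaN.
    """
    adm = admissions[admissions["patient_id"].isin(patients["patient_id"])]
    first_adm = first_qualifying_admissions(adm, code_prefix)
    n_cases = len(first_adm)
    if n_cases == 0:
        return ValidationSummary(0, np.nan, np.nan, np.nan, np.nan)

    matches = match_all_codes(events, prescriptions, codelist, include_probable)
    first_code = matches.groupby("patient_id")["date"].min()

    df = first_adm.rename("admission").to_frame()
    df["code"] = first_code.reindex(df.index)
    with_code = df["code"].notna()
    timing = pd.Series("", index=df.index, dtype=object)
    timing[with_code & (df["code"] < df["admission"])] = "BEFORE"
    timing[
        with_code
        & (df["code"] >= df["admission"])
        & (df["code"] <= df["admission"] + pd.Timedelta(days=30))
    ] = "WITHIN_30_AFTER"
    timing[with_code & (df["code"] > df["admission"] + pd.Timedelta(days=30))] = "LATER"

    return ValidationSummary(
        n_hospital_cases=n_cases,
        fraction_with_primary_care_code=float(with_code.mean()),
        fraction_before=float((timing == "BEFORE").mean()),
        fraction_within_30_after=float((timing == "WITHIN_30_AFTER").mean()),
        fraction_later=float((timing == "LATER").mean()),
    )
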