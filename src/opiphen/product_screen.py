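"""Demographic screen separating OAT products from analgesic products.

Methadone and buprenorphine are prescribed both as opioid agonist therapy
(OAT) and for pain.  Prescription records carry no reliable dose or
indication, but the two patient populations differ sharply: OAT recipients
are mostly younger men, analgesic recipients mostly older women.  The screen
summarises the age and sex of each product's patients at their first
prescription of that product and excludes products whose demographics look
analgesic: more than half female, lower age quartile under 18, or upper age
quartile over 64 (strict inequalities; exact ties pass).

A per-product override mechanism models the final manual review by a
prescribing professional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import imputed_birth_date, age_in_completed_years

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProductDemographics:
    """Age/sex profile of one product's patients at first prescription."""

    product_code: str
    n_patients: int
    fraction_female: float
    age_q1: float
    age_q3: float

    def __post_init__(self) -> None:
        if self.n_patients >= 1 and self.age_q1 > self.age_q3:
            raise ValueError("age_q1 must be <= age_q3")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValueError("fraction_female must be in [0, 1]")


def first_prescriptions(
    prescriptions: pd.DataFrame, patients: pd.DataFrame
) -> pd.DataFrame:
    """Earliest prescription of each product per patient, with demographics.

    Parameters
    ----------
    prescriptions
        Columns ``patient_id``, ``date``, ``product_code``.
    patients
        Registry with ``patient_id``, ``sex``, ``year_of_birth``.

    Returns
    -------
    DataFrame
        One row per ``(product_code, patient_id)``: columns ``product_code``,
        ``patient_id``, ``sex``, ``age_at_first_prescription`` (completed
        years at the earliest prescription date, against the mid-year imputed
        birth date).  Prescriptions for unknown patients are skipped with a
        logged warning count; a prescription dated before the imputed birth
        date is an error naming the patient.
    """
    rx = prescriptions.copy()
    rx["date"] = pd.to_datetime(rx["date"])
    known = rx["patient_id"].isin(patients["patient_id"])
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("skipped %d prescriptions for unknown patients", n_unknown)
        rx = rx[known]
    first = (
        rx.sort_values("date", kind="stable")
        .drop_duplicates(subset=["product_code", "patient_id"], keep="first")
        .merge(patients[["patient_id", "sex", "year_of_birth"]], on="patient_id")
    )
    birth = imputed_birth_date(first["year_of_birth"])
    if (first["date"].to_numpy() < birth.to_numpy()).any():
        bad = first.loc[first["date"].to_numpy() < birth.to_numpy(), "patient_id"].iloc[0]
        raise ValueError(
            f"prescription dated before imputed birth date for patient {bad!r}"
        )
    first["age_at_first_prescription"] = age_in_completed_years(
        birth, first["date"]
    )
    return first[
        ["product_code", "patient_id", "sex", "age_at_first_prescription"]
    ].reset_index(drop=True)


def summarize_product(rows: pd.DataFrame) -> ProductDemographics:
    """Summarise one product's first-prescription rows.

    Quartiles use linear interpolation between order statistics.
    """
    if len(rows) == 0:
        raise ValueError("cannot summarise a product with zero first prescriptions")
    codes = rows["product_code"].unique()
    if len(codes) != 1:
        raise ValueError(f"rows span multiple products: {sorted(codes)}")
    ages = rows["age_at_first_prescription"].to_numpy(dtype=float)
    q1, q3 = np.percentile(ages, [25, 75])
    return ProductDemographics(
        product_code=str(codes[0]),
        n_patients=len(rows),
        fraction_female=float((rows["sex"] == "F").mean()),
        age_q1=float(q1),
        age_q3=float(q3),
    )


def summarize_products(first_rx: pd.DataFrame) -> list[ProductDemographics]:
    """Summarise every product present in a first-prescriptions table."""
    return [
        summarize_product(grp)
        for _, grp in first_rx.groupby("product_code", sort=True)
    ]


def is_oat_like(s: ProductDemographics) -> bool:
    """Demographic rule: excluded iff >50% female, Q1 age <18, or Q3 age >64."""
    return not (s.fraction_female > 0.5 or s.age_q1 < 18 or s.age_q3 > 64)


def apply_oat_filter(
    summaries: list[ProductDemographics],
    overrides: Mapping[str, str] | None = None,
    min_n_patients: int = 1,
) -> pd.DataFrame:
    """Partition products into OAT_PRODUCT and EXCLUDED.

    Parameters
    ----------
    summaries
        Per-product demographics.
    overrides
        Optional per-product ``{"keep" | "drop"}`` decisions modelling the
        manual clinician review; applied last and logged.  An override for a
        product not in ``summaries`` is an error.
    min_n_patients
        Products with fewer patients are flagged ``needs_review`` rather than
        auto-classified (decision column still populated by the rule so the
        partition stays exhaustive).

    Returns
    -------
    DataFrame
        Columns ``product_code``, ``n_patients``, ``fraction_female``,
        ``age_q1``, ``age_q3``, ``decision`` (OAT_PRODUCT/EXCLUDED),
        ``override_applied``, ``needs_review``.
    """
    overrides = dict(overrides or {})
    known = {s.product_code for s in summaries}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"overrides for unknown products: {sorted(unknown)}")
    rows = []
    for s in summaries:
        decision = "OAT_PRODUCT" if is_oat_like(s) else "EXCLUDED"
        override_applied = False
        if s.product_code in overrides:
            action = overrides[s.product_code]
            if action not in ("keep", "drop"):
                raise ValueError(
                    f"override for {s.product_code!r} must be 'keep' or 'drop', got {action!r}"
                )
            decision = "OAT_PRODUCT" if action == "keep" else "EXCLUDED"
            override_applied = True
            logger.info("override %s -> %s", s.product_code, decision)
        rows.append(
            {
                "product_code": s.product_code,
                "n_patients": s.n_patients,
                "fraction_female": s.fraction_female,
                "age_q1": s.age_q1,
                "age_q3": s.age_q3,
                "decision": decision,
                "override_applied": override_applied,
                "needs_review": s.n_patients < min_n_patients,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "product_code",
            "n_patients",
            "fraction_female",
            "age_q1",
            "age_q3",
            "decision",
            "override_applied",
            "needs_review",
        ],
    )


def screen_products(
    prescriptions: pd.DataFrame,
    patients: pd.DataFrame,
    overrides: Mapping[str, str] | None = None,
    min_n_patients: int = 1,
) -> pd.DataFrame:
    """End-to-end product screen: first prescriptions → summaries → filter."""
    first = first_prescriptions(prescriptions, patients)
    return apply_oat_filter(
        summarize_products(first), overrides=overrides, min_n_patients=min_n_patients
    )
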