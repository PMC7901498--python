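"""Person-time expansion and indirectly standardised mortality.

Follow-up for each cohort member is expanded to days and accumulated in
Lexis strata of sex × single year of attained age × calendar year.  Expected
deaths come from applying reference-population mortality rates (deaths per
person-year) to each stratum's person-time; the standardised mortality ratio
(SMR) is observed/expected with an exact Poisson confidence interval from
chi-square quantiles:

    lower = chi2.ppf(alpha/2, 2*O) / 2 / E        (0 when O = 0)
    upper = chi2.ppf(1 - alpha/2, 2*(O+1)) / 2 / E

Crude mortality rates (CMR, per 1000 person-years) use the same exact bounds
on the death count.

Conventions
-----------
* Follow-up is half-open [entry, exit); a member contributes exit − entry
  days.  For decedents whose exit equals the death date, the interval is
  extended one day so the death day contributes its own risk time and the
  death lands in a stratum.
* Because birth dates are imputed to 1 July, age and calendar year are both
  constant on every calendar half-year, which the expansion exploits; it is
  exactly equivalent to a day-by-day loop.
* Expected deaths convert days to years with the exact calendar-year length
  (365 or 366); the headline crude rate uses 365.25 days per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

DAYS_PER_YEAR = 365.25

#: attained-age bands used by the stratified mortality table
DEFAULT_AGE_BANDS: tuple[tuple[int, int | None], ...] = (
    (18, 29),
    (30, 39),
    (40, 49),
    (50, 64),
    (65, None),
)


def poisson_exact_ci(observed: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) confidence bounds for a Poisson count."""
    if observed < 0:
        raise ValueError("observed must be >= 0")
    lo = 0.0 if observed == 0 else float(chi2.ppf(alpha / 2, 2 * observed) / 2)
    hi = float(chi2.ppf(1 - alpha / 2, 2 * (observed + 1)) / 2)
    return lo, hi


@dataclass(frozen=True)
class SMRResult:
    """Standardised mortality ratio with exact Poisson confidence interval."""

    observed: int
    expected: float
    smr: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __str__(self) -> str:
        pct = round((1 - self.alpha) * 100)
        return (
            f"SMR {self.smr:.2f} ({pct:g}% CI {self.ci_low:.2f}-{self.ci_high:.2f}; "
            f"O={self.observed}, E={self.expected:.1f})"
        )


@dataclass(frozen=True)
class CMRResult:
    """Crude mortality rate per 1000 person-years with exact Poisson CI."""

    deaths: int
    person_years: float
    rate_per_1000: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __str__(self) -> str:
        pct = round((1 - self.alpha) * 100)
        return (
            f"CMR {self.rate_per_1000:.2f} per 1000 py "
            f"({pct:g}% CI {self.ci_low:.2f}-{self.ci_high:.2f}; "
            f"deaths={self.deaths}, py={self.person_years:.0f})"
        )


def smr(observed: int, expected: float, alpha: float = 0.05) -> SMRResult:
    """Observed/expected deaths with exact Poisson confidence interval."""
    if expected <= 0:
        raise ValueError("expected deaths must be positive")
    if observed < 0:
        raise ValueError("observed deaths must be >= 0")
    lo, hi = poisson_exact_ci(observed, alpha)
    return SMRResult(
        observed=int(observed),
        expected=float(expected),
        smr=observed / expected,
        ci_low=lo / expected,
        ci_high=hi / expected,
        alpha=alpha,
    )


def crude_rate_from_person_years(
    deaths: int, person_years: float, alpha: float = 0.05
) -> CMRResult:
    """Deaths per 1000 person-years with exact Poisson CI on the count."""
    if person_years <= 0:
        raise ValueError("person-time must be positive")
    lo, hi = poisson_exact_ci(deaths, alpha)
    scale = 1000.0 / person_years
    return CMRResult(
        deaths=int(deaths),
        person_years=float(person_years),
        rate_per_1000=deaths * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
        alpha=alpha,
    )


def crude_rate(deaths: int, person_days: int, alpha: float = 0.05) -> CMRResult:
    """Crude rate from person-days (converted at 365.25 days/year)."""
    return crude_rate_from_person_years(deaths, person_days / DAYS_PER_YEAR, alpha)


def truncate_for_registration_lag(
    members: pd.DataFrame,
    linkage_end: pd.Timestamp | str | None = None,
    lag_months: int = 6,
    cap_date: pd.Timestamp | str | None = None,
) -> pd.DataFrame:
    """Cap follow-up before the linkage cut-off to avoid registration lag.

    Deaths from drug poisoning involve coroners and are registered late, so
    follow-up stops ``lag_months`` calendar months before the linkage end
    (or at an explicit ``cap_date``, which takes precedence).  Exit is capped
    at the cap date; members left with no follow-up are dropped; deaths on or
    after the cap fall outside the half-open interval and are uncounted.
    """
    if cap_date is None:
        if linkage_end is None:
            raise ValueError("provide linkage_end or cap_date")
        if lag_months < 0:
            raise ValueError("lag_months must be >= 0")
        cap_date = pd.Timestamp(linkage_end) - pd.DateOffset(months=lag_months)
    cap = pd.Timestamp(cap_date)
    out = members.copy()
    out["exit"] = out["exit"].clip(upper=cap)
    out["died"] = out["died"] & (out["death_date"] < cap)
    return out[out["entry"] < out["exit"]].reset_index(drop=True)


def _effective_end(members: pd.DataFrame) -> pd.Series:
    """Interval end including the death day for decedents (exit = death)."""
    end = members["exit"].copy()
    extend = members["died"] & (members["death_date"] >= members["exit"])
    end[extend] = members.loc[extend, "death_date"] + pd.Timedelta(days=1)
    return end


def expand_person_time(members: pd.DataFrame) -> pd.DataFrame:
    """Expand follow-up into sex × attained-age × calendar-year strata.

    Each day of each member's follow-up is assigned to exactly one stratum;
    the death (if any) increments ``observed_deaths`` in the stratum of the
    death day.  Total days across strata equal total follow-up exactly
    (asserted on every run).

    Parameters
    ----------
    members
        Columns ``sex``, ``year_of_birth``, ``entry``, ``exit``, ``died``,
        ``death_date``.

    Returns
    -------
    DataFrame
        Columns ``sex``, ``age``, ``year``, ``days``, ``observed_deaths``,
        sorted by (sex, age, year).
    """
    if len(members) == 0:
        return pd.DataFrame(columns=["sex", "age", "year", "days", "observed_deaths"])
    if (members["exit"] <= members["entry"]).any():
        bad = members.loc[members["exit"] <= members["entry"], "patient_id"]
        raise ValueError(
            f"members with non-positive follow-up should have been filtered: "
            f"{list(bad.iloc[:5])}"
        )

    entry = members["entry"].to_numpy(dtype="datetime64[D]").astype(np.int64)
    end = _effective_end(members).to_numpy(dtype="datetime64[D]").astype(np.int64)
    yob = members["year_of_birth"].to_numpy(dtype=np.int64)
    sex = members["sex"].to_numpy()

    y0 = int(members["entry"].min().year)
    y1 = int(_effective_end(members).max().year) + 1

    parts: list[pd.DataFrame] = []
    for year in range(y0, y1):
        jan1 = np.datetime64(f"{year}-01-01", "D").astype(np.int64)
        jul1 = np.datetime64(f"{year}-07-01", "D").astype(np.int64)
        jan1_next = np.datetime64(f"{year + 1}-01-01", "D").astype(np.int64)
        # ages are constant on [1 Jan, 1 Jul) and [1 Jul, 1 Jan) because
        # every birth date is imputed to 1 July
        for a, b, age_off in ((jan1, jul1, -1), (jul1, jan1_next, 0)):
            days = np.minimum(end, b) - np.maximum(entry, a)
            keep = days > 0
            if not keep.any():
                continue
            parts.append(
                pd.DataFrame(
                    {
                        "sex": sex[keep],
                        "age": year - yob[keep] + age_off,
                        "year": year,
                        "days": days[keep],
                        "observed_deaths": 0,
                    }
                )
            )

    died = members["died"].to_numpy(dtype=bool)
    if died.any():
        death = members.loc[members["died"], "death_date"]
        dyear = death.dt.year.to_numpy(dtype=np.int64)
        before_birthday = (death.dt.month < 7).to_numpy()
        parts.append(
            pd.DataFrame(
                {
                    "sex": sex[died],
                    "age": dyear - yob[died] - before_birthday.astype(np.int64),
                    "year": dyear,
                    "days": 0,
                    "observed_deaths": 1,
                }
            )
        )

    strata = (
        pd.concat(parts, ignore_index=True)
        .groupby(["sex", "age", "year"], as_index=False)[["days", "observed_deaths"]]
        .sum()
        .sort_values(["sex", "age", "year"], kind="stable")
        .reset_index(drop=True)
    )
    total = int(strata["days"].sum())
    expected_total = int((end - entry).sum())
    assert total == expected_total, (
        f"person-time not conserved: {total} stratum days vs {expected_total} follow-up days"
    )
    return strata


def _days_in_year(year: np.ndarray | int):
    y = np.asarray(year)
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    return np.where(leap, 366, 365)


def expected_deaths(strata: pd.DataFrame, rate_table: pd.DataFrame) -> float:
    """Expected deaths = Σ (stratum days / days in that year) × reference rate.

    Every stratum with positive person-time must have a rate-table entry
    (``sex, age, year, rate`` in deaths per person-year); missing cells are a
    hard error listing every missing (sex, age, year) key.
    """
    occupied = strata[strata["days"] > 0]
    merged = occupied.merge(
        rate_table[["sex", "age", "year", "rate"]], on=["sex", "age", "year"], how="left"
    )
    missing = merged["rate"].isna()
    if missing.any():
        cells = [
            (r.sex, int(r.age), int(r.year))
            for r in merged.loc[missing, ["sex", "age", "year"]].itertuples(index=False)
        ]
        raise ValueError(f"no reference rate for {len(cells)} strata: {cells}")
    person_years = merged["days"].to_numpy() / _days_in_year(merged["year"].to_numpy())
    return float((person_years * merged["rate"].to_numpy()).sum())


def _band_label(band: tuple[int, int | None]) -> str:
    lo, hi = band
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


def _assign_band(ages: np.ndarray, bands) -> np.ndarray:
    out = np.full(len(ages), "", dtype=object)
    for band in bands:
        lo, hi = band
        mask = ages >= lo if hi is None else (ages >= lo) & (ages <= hi)
        out[mask] = _band_label(band)
    return out


def smr_table(
    members: pd.DataFrame,
    rate_table: pd.DataFrame,
    age_bands: tuple[tuple[int, int | None], ...] = DEFAULT_AGE_BANDS,
    alpha: float = 0.05,
    label: str = "",
) -> pd.DataFrame:
    """Mortality table stratified by sex and attained-age band.

    One row per sex ('F', 'M', 'Both') × (band ∪ 'All ages'): number at
    baseline (by age at entry; blank for bands above the entry age limit),
    follow-up years, observed and expected deaths, CMR and SMR with exact
    Poisson intervals.  All-ages rows aggregate the band rows exactly (days,
    observed and expected deaths each sum).
    """
    strata = expand_person_time(members)
    strata = strata.assign(band=_assign_band(strata["age"].to_numpy(), age_bands))
    entry_band = _assign_band(members["age_at_entry"].to_numpy(), age_bands)

    rows = []
    sex_groups: list[tuple[str, pd.DataFrame, np.ndarray]] = [
        ("F", strata[strata["sex"] == "F"], entry_band[(members["sex"] == "F").to_numpy()]),
        ("M", strata[strata["sex"] == "M"], entry_band[(members["sex"] == "M").to_numpy()]),
        ("Both", strata, entry_band),
    ]
    band_labels = [_band_label(b) for b in age_bands]
    for sex_label, sub, ebands in sex_groups:
        if len(sub) == 0:
            continue
        for band in band_labels + ["All ages"]:
            cell = sub if band == "All ages" else sub[sub["band"] == band]
            days = int(cell["days"].sum())
            if days == 0 and band != "All ages":
                continue
            observed = int(cell["observed_deaths"].sum())
            e = expected_deaths(cell, rate_table) if days > 0 else np.nan
            n_base = (
                len(ebands)
                if band == "All ages"
                else int((ebands == band).sum()) or None
            )
            cmr = crude_rate(observed, days, alpha) if days > 0 else None
            s = smr(observed, e, alpha) if e and e > 0 else None
            rows.append(
                {
                    "label": label,
                    "sex": sex_label,
                    "age_band": band,
                    "n_baseline": n_base,
                    "follow_up_years": days / DAYS_PER_YEAR,
                    "observed": observed,
                    "expected": e,
                    "cmr": cmr.rate_per_1000 if cmr else np.nan,
                    "cmr_low": cmr.ci_low if cmr else np.nan,
                    "cmr_high": cmr.ci_high if cmr else np.nan,
                    "smr": s.smr if s else np.nan,
                    "smr_low": s.ci_low if s else np.nan,
                    "smr_high": s.ci_high if s else np.nan,
                }
            )
    return pd.DataFrame(rows)
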