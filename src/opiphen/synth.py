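"""Synthetic primary-care EHR generator with known ground truth.

Real UK primary-care extracts are licence-restricted, so every pipeline
stage here is exercised on generated data shaped like a two-subpopulation
registry:

* *phenotype-positive* patients (people with a history of illicit opioid
  use): ~69% male, age at first use centred in the mid-30s and drifting
  older with calendar year, deprivation-skewed, mostly current smokers, and
  a mortality hazard several times the reference population (default 6.6);
* *background* patients: older, majority female, reference-level mortality,
  and the recipients of confusable analgesic prescriptions (transdermal
  buprenorphine patches prescribed predominantly to older women).

Deaths are simulated day-by-day from the generated reference rate table
(rate/days-in-year per day, multiplied by the hazard ratio for positives),
using the same 1-July birth-date convention the analysis modules assume, so
the standardisation pipeline is exactly calibrated against the generator.

All randomness flows from a single seed through named substreams, one per
output table, so regenerating one table does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ENGLAND_REGIONS
from .codelist import Codelist, example_codelist, save_codelist

#: definite clinical codes, OAT products and the confusable product drawn
#: from the bundled illustrative codelist
DEFINITE_CODES = ("R0001", "R0002", "R0003")
PROBABLE_CODES = ("R0004",)
OAT_PRODUCTS = ("P0001", "P0002", "P0004")
CONFUSABLE_PRODUCT = "P0003"

SMOKING_CODES = {"CURRENT": "SM001", "EX": "SM002", "NEVER": "SM003"}
FLAG_CODES = {"homelessness": "FL001", "prison": "FL002", "alcohol_dependence": "FL003"}


def smoking_codelist() -> pd.DataFrame:
    """Smoking codelist (code → CURRENT/EX/NEVER) matching generated events."""
    return pd.DataFrame(
        {
            "code_id": list(SMOKING_CODES.values()),
            "terminology": "READ",
            "status": list(SMOKING_CODES.keys()),
        }
    )


def flag_codelists() -> dict[str, pd.DataFrame]:
    """History-flag codelists (homelessness, prison, alcohol dependence)."""
    return {
        name: pd.DataFrame({"code_id": [code], "terminology": ["READ"]})
        for name, code in FLAG_CODES.items()
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Proportion and rate defaults are the characteristics the generated
    cohort is meant to exhibit: 69% male positives, median age at first use
    in the mid-30s drifting older over calendar time, 42% of positives in
    the most deprived quintile, smoking 76/10/6/8 current/ex/never/no
    records, mortality hazard ratio 6.6 against the reference rates, and
    0.88 sensitivity of the primary-care record among hospital cases.
    """

    seed: int = 0
    n_patients: int = 5000
    phenotype_prevalence: float = 0.3
    male_fraction_positive: float = 0.69
    female_fraction_background: float = 0.55
    #: lognormal age at first use: median ~32 at the study start plus drift
    age_median_positive: float = 32.0
    age_sigma_positive: float = 0.28
    entry_age_drift: float = 0.35  # years of age per calendar year
    imd_weights_positive: tuple[float, ...] = (0.066, 0.110, 0.159, 0.243, 0.422)
    smoking_positive: tuple[float, ...] = (0.76, 0.10, 0.06, 0.08)  # cur/ex/nev/none
    smoking_background: tuple[float, ...] = (0.20, 0.25, 0.45, 0.10)
    flag_rates_positive: tuple[float, ...] = (0.05, 0.07, 0.18)  # homeless/prison/alcohol
    flag_rates_background: tuple[float, ...] = (0.005, 0.005, 0.03)
    hazard_ratio: float = 6.6
    #: phenotype evidence mix among recorded positives (clinical only /
    #: product only / both), mirroring the observed overlap
    evidence_split: tuple[float, ...] = (0.60, 0.10, 0.30)
    phenotype_recording: float = 1.0  # fraction of positives with any record
    hospital_sensitivity: float = 0.88
    admission_fraction_positive: float = 0.25
    confusable_n_prescriptions: int = 400
    confusable_female_fraction: float = 0.80
    confusable_age_mean: float = 62.0
    confusable_age_sd: float = 10.0
    region_nonengland_fraction: float = 0.02
    study_start: pd.Timestamp = pd.Timestamp("1997-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2018-12-31")
    #: reference mortality at age 40 (deaths/person-year) and log-slope per
    #: year of age; male rates sit above female rates
    rate_at_40_male: float = 0.0022
    rate_at_40_female: float = 0.0014
    rate_log_slope: float = 0.085
    rate_age_range: tuple[int, int] = (15, 95)

    def __post_init__(self) -> None:
        for name in (
            "phenotype_prevalence",
            "male_fraction_positive",
            "female_fraction_background",
            "phenotype_recording",
            "hospital_sensitivity",
            "confusable_female_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("imd_weights_positive", "smoking_positive", "smoking_background",
                     "evidence_split"):
            w = getattr(self, name)
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named output table."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         zlib.crc32(name.encode())]))


def generate_reference_rates(config: SimulationConfig) -> pd.DataFrame:
    """Reference mortality rate table covering the whole study window.

    Rates are exponential in age (log-linear), sex-differentiated, constant
    over calendar years, and cover every (sex, age, year) cell from
    ``rate_age_range`` and two years beyond the study window on either side.
    Doubling ``rate_at_40_*`` doubles every rate of that sex.
    """
    lo, hi = config.rate_age_range
    ages = np.arange(lo, hi + 1)
    years = np.arange(config.study_start.year - 2, config.study_end.year + 3)
    frames = []
    for sex, base in (("M", config.rate_at_40_male), ("F", config.rate_at_40_female)):
        rate = base * np.exp(config.rate_log_slope * (ages - 40.0))
        grid = pd.DataFrame(
            {
                "sex": sex,
                "age": np.repeat(ages, len(years)),
                "year": np.tile(years, len(ages)),
                "rate": np.repeat(rate, len(years)),
            }
        )
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)


def _random_dates(rng, start: pd.Timestamp, end: pd.Timestamp, size: int) -> np.ndarray:
    lo = np.datetime64(start, "D").astype(np.int64)
    hi = np.datetime64(end, "D").astype(np.int64)
    return rng.integers(lo, hi + 1, size=size).astype("datetime64[D]")


def generate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the patient registry and its ground truth.

    Returns ``(patients, truth)``: the registry with the standard columns
    (death dates filled in later by :func:`generate_events`), and per-patient
    ground truth (phenotype flag, true first-use date, hazard multiplier).
    Deterministic given ``config.seed``.
    """
    rng = _substream(config.seed, "population")
    n = config.n_patients
    positive = rng.random(n) < config.phenotype_prevalence

    sex = np.where(
        positive,
        np.where(rng.random(n) < config.male_fraction_positive, "M", "F"),
        np.where(rng.random(n) < config.female_fraction_background, "F", "M"),
    )

    # positives: first illicit use at a lognormal age that drifts older with
    # the first-use calendar year (the population is ageing)
    first_use = _random_dates(rng, config.study_start, config.study_end, n)
    use_year = first_use.astype("datetime64[Y]").astype(int) + 1970
    age_at_use = np.exp(
        rng.normal(np.log(config.age_median_positive), config.age_sigma_positive, n)
    ) + config.entry_age_drift * (use_year - config.study_start.year)
    age_at_use = np.clip(age_at_use, 16.0, 70.0)

    yob = np.where(
        positive,
        use_year - np.round(age_at_use).astype(int),
        # background: broad adult age mix, skewed older
        config.study_start.year - rng.integers(20, 80, size=n),
    )

    # registration window: start anywhere in the study period (or slightly
    # before), lasting 1-20 years, truncated to the data-collection horizon
    data_start = _random_dates(
        rng, config.study_start - pd.DateOffset(years=3), config.study_end - pd.Timedelta(days=365), n
    )
    duration_days = rng.integers(365, 20 * 365, size=n)
    data_end = np.minimum(
        data_start + duration_days.astype("timedelta64[D]"),
        np.datetime64(config.study_end + pd.DateOffset(years=1), "D"),
    )

    region_pool = np.array(ENGLAND_REGIONS)
    region = region_pool[rng.integers(0, len(region_pool), size=n)].astype(object)
    non_england = rng.random(n) < config.region_nonengland_fraction
    region[non_england] = "Wales"

    imd = np.where(
        positive,
        rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.imd_weights_positive)),
        rng.integers(1, 6, size=n),
    )

    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i:06d}" for i in range(n)],
            "sex": sex,
            "year_of_birth": yob.astype(int),
            "region": region,
            "imd_quintile": imd,
            "data_start": pd.to_datetime(data_start),
            "data_end": pd.to_datetime(data_end),
            "death_date": pd.NaT,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "positive": positive,
            "true_first_use": pd.to_datetime(np.where(positive, first_use, np.datetime64("NaT"))),
            "hazard_multiplier": np.where(positive, config.hazard_ratio, 1.0),
        }
    )
    return patients, truth


def _simulate_deaths(
    patients: pd.DataFrame,
    truth: pd.DataFrame,
    rates: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Daily Bernoulli death simulation over each registration window.

    Within each calendar half-year the daily probability is constant
    (annual rate / days in year, times the hazard multiplier), so the
    day-by-day Bernoulli process is sampled exactly with one uniform draw
    per patient-segment via the geometric inverse CDF.
    """
    lo, hi = config.rate_age_range
    years = np.arange(rates["year"].min(), rates["year"].max() + 1)
    rate_grid = {}
    for sex in ("M", "F"):
        sub = rates[rates["sex"] == sex].pivot(index="age", columns="year", values="rate")
        rate_grid[sex] = sub.reindex(index=np.arange(lo, hi + 1), columns=years).to_numpy()

    start = patients["data_start"].to_numpy(dtype="datetime64[D]").astype(np.int64)
    end = patients["data_end"].to_numpy(dtype="datetime64[D]").astype(np.int64)
    yob = patients["year_of_birth"].to_numpy()
    is_male = (patients["sex"] == "M").to_numpy()
    mult = truth["hazard_multiplier"].to_numpy()

    n = len(patients)
    death = np.full(n, np.iinfo(np.int64).max)
    alive = np.ones(n, dtype=bool)
    y0 = int(patients["data_start"].min().year)
    y1 = int(patients["data_end"].max().year)
    for year in range(y0, y1 + 1):
        jan1 = np.datetime64(f"{year}-01-01", "D").astype(np.int64)
        jul1 = np.datetime64(f"{year}-07-01", "D").astype(np.int64)
        jan1n = np.datetime64(f"{year + 1}-01-01", "D").astype(np.int64)
        diy = (jan1n - jan1)
        for a, b, age_off in ((jan1, jul1, -1), (jul1, jan1n, 0)):
            seg_a = np.maximum(start, a)
            seg_b = np.minimum(end, b)
            d = seg_b - seg_a
            active = alive & (d > 0)
            if not active.any():
                continue
            idx = np.flatnonzero(active)
            age = np.clip(year - yob[idx] + age_off, lo, hi) - lo
            yi = year - years[0]
            rate = np.where(
                is_male[idx],
                rate_grid["M"][age, yi],
                rate_grid["F"][age, yi],
            )
            p = np.clip(rate * mult[idx] / diy, 0.0, 0.5)
            u = rng.random(len(idx))
            with np.errstate(divide="ignore", invalid="ignore"):
                k = np.floor(np.log1p(-u) / np.log1p(-p))
            k = np.where(p > 0, k, np.inf)
            hit = k < d[idx]
            k = np.where(np.isfinite(k), k, 0).astype(np.int64)
            died_idx = idx[hit]
            death[died_idx] = seg_a[died_idx] + k[hit]
            alive[died_idx] = False
    out = pd.Series(pd.NaT, index=patients.index, dtype="datetime64[ns]")
    has = death < np.iinfo(np.int64).max
    out[has] = pd.to_datetime(death[has].astype("datetime64[D]"))
    return out


def generate_events(
    patients: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rates: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate clinical events, prescriptions, admissions and deaths.

    Returns a dict with keys ``patients`` (registry with death dates
    filled), ``events``, ``prescriptions``, ``admissions``.  Phenotype
    evidence goes only to ground-truth positives; confusable analgesic
    prescriptions go predominantly to older female background patients;
    deaths follow the reference rates times the per-patient hazard
    multiplier.
    """
    rates = generate_reference_rates(config) if rates is None else rates
    rng_d = _substream(config.seed, "deaths")
    patients = patients.copy()
    patients["death_date"] = _simulate_deaths(patients, truth, rates, config, rng_d)
    effective_end = patients["death_date"].fillna(patients["data_end"])

    rng = _substream(config.seed, "events")
    pos = truth["positive"].to_numpy()
    n = len(patients)

    events_rows: list[pd.DataFrame] = []
    rx_rows: list[pd.DataFrame] = []

    # --- phenotype evidence for positives -------------------------------
    recorded = pos & (rng.random(n) < config.phenotype_recording)
    kind = np.full(n, "", dtype=object)
    kinds = np.array(["clinical", "product", "both"])
    kind[recorded] = rng.choice(kinds, size=int(recorded.sum()), p=np.asarray(config.evidence_split))

    first_use = truth["true_first_use"].to_numpy(dtype="datetime64[D]").astype("float64")
    delay = rng.exponential(365.0, size=n)
    record_day = first_use + np.round(delay)
    # clamp the first record inside the patient's plausible horizon
    horizon = effective_end.to_numpy(dtype="datetime64[D]").astype("float64")
    record_day = np.minimum(record_day, horizon)
    rd = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    rd[recorded] = np.round(record_day[recorded]).astype(np.int64).astype("datetime64[D]")
    record_date = pd.to_datetime(rd)

    has_clin = recorded & np.isin(kind, ("clinical", "both"))
    has_prod = recorded & np.isin(kind, ("product", "both"))

    idx = np.flatnonzero(has_clin)
    if len(idx):
        codes = rng.choice(np.array(DEFINITE_CODES), size=len(idx))
        events_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"].to_numpy()[idx],
                    "date": record_date[idx],
                    "code_id": codes,
                    "terminology": "READ",
                }
            )
        )
    idx = np.flatnonzero(has_prod)
    if len(idx):
        # a short run of OAT prescriptions starting at the first record
        reps = rng.integers(1, 9, size=len(idx))
        pat = np.repeat(patients["patient_id"].to_numpy()[idx], reps)
        base = np.repeat(record_date[idx].to_numpy(dtype="datetime64[D]").astype("float64"), reps)
        offs = rng.integers(0, 3 * 365, size=len(pat))
        prod = rng.choice(np.array(OAT_PRODUCTS), size=len(pat))
        rx_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pat,
                    "date": pd.to_datetime((base + offs).astype("datetime64[D]")),
                    "product_code": prod,
                }
            )
        )

    # --- confusable analgesic product (transdermal patch) ---------------
    bg = np.flatnonzero(~pos)
    n_conf = min(config.confusable_n_prescriptions, len(bg))
    if n_conf:
        bg_sex = patients["sex"].to_numpy()[bg]
        mid_year = (config.study_start.year + config.study_end.year) // 2
        bg_age = mid_year - patients["year_of_birth"].to_numpy()[bg]
        age_w = np.exp(-0.5 * ((bg_age - config.confusable_age_mean) / config.confusable_age_sd) ** 2)
        age_w += 1e-12
        chosen = []
        for sex_code, frac in (("F", config.confusable_female_fraction),
                               ("M", 1.0 - config.confusable_female_fraction)):
            pool = bg[bg_sex == sex_code]
            w = age_w[bg_sex == sex_code]
            k = min(int(round(n_conf * frac)), len(pool))
            if k:
                chosen.append(rng.choice(pool, size=k, replace=False, p=w / w.sum()))
        conf_idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
        if len(conf_idx):
            dates = _random_dates(rng, config.study_start, config.study_end, len(conf_idx))
            rx_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[conf_idx],
                        "date": pd.to_datetime(dates),
                        "product_code": CONFUSABLE_PRODUCT,
                    }
                )
            )

    # --- smoking records and history flags ------------------------------
    smoke_p = np.where(pos[:, None],
                       np.asarray(config.smoking_positive),
                       np.asarray(config.smoking_background))
    u = rng.random(n)
    cum = np.cumsum(smoke_p, axis=1)
    smoke_cat = (u[:, None] > cum).sum(axis=1)  # 0 cur, 1 ex, 2 never, 3 none
    statuses = np.array(["CURRENT", "EX", "NEVER"])
    has_smoke = smoke_cat < 3
    idx = np.flatnonzero(has_smoke)
    if len(idx):
        start_f = patients["data_start"].to_numpy(dtype="datetime64[D]").astype("float64")
        span = np.maximum(horizon - start_f, 1.0)
        date = np.round(start_f + rng.random(n) * span).astype(np.int64)
        events_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"].to_numpy()[idx],
                    "date": pd.to_datetime(date[idx].astype("datetime64[D]")),
                    "code_id": np.array([SMOKING_CODES[s] for s in statuses[smoke_cat[idx]]]),
                    "terminology": "READ",
                }
            )
        )
    for (name, code), p_pos, p_bg in zip(
        FLAG_CODES.items(), config.flag_rates_positive, config.flag_rates_background
    ):
        has_flag = rng.random(n) < np.where(pos, p_pos, p_bg)
        idx = np.flatnonzero(has_flag)
        if len(idx):
            dates = _random_dates(rng, config.study_start, config.study_end, len(idx))
            events_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[idx],
                        "date": pd.to_datetime(dates),
                        "code_id": code,
                        "terminology": "READ",
                    }
                )
            )

    # --- hospital admissions with F11 diagnoses -------------------------
    rng_h = _substream(config.seed, "admissions")
    adm_rows = []
    rec_pos_idx = np.flatnonzero(recorded)
    n_adm_pos = int(round(config.admission_fraction_positive * len(rec_pos_idx)))
    if config.hospital_sensitivity > 0:
        n_adm_total = int(round(n_adm_pos / config.hospital_sensitivity))
    else:
        n_adm_total = n_adm_pos
    n_adm_bg = n_adm_total - n_adm_pos
    chosen_pos = rng_h.choice(rec_pos_idx, size=min(n_adm_pos, len(rec_pos_idx)), replace=False)
    bg_pool = np.flatnonzero(~recorded)
    chosen_bg = rng_h.choice(bg_pool, size=min(n_adm_bg, len(bg_pool)), replace=False)
    for chosen in (chosen_pos, chosen_bg):
        if len(chosen) == 0:
            continue
        dates = _random_dates(rng_h, config.study_start, config.study_end, len(chosen))
        extra = rng_h.choice(np.array(["", ";J45.0", ";F10.2", ";K70.3"]), size=len(chosen))
        adm_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"].to_numpy()[chosen],
                    "admission_date": pd.to_datetime(dates),
                    "diagnosis_codes": np.char.add("F11.2", extra.astype(str)),
                }
            )
        )

    def _cat(rows: list[pd.DataFrame], cols: list[str]) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame(columns=cols)
        return (
            pd.concat(rows, ignore_index=True)
            .sort_values(cols[:2], kind="stable")
            .reset_index(drop=True)
        )

    return {
        "patients": patients,
        "events": _cat(events_rows, ["patient_id", "date", "code_id", "terminology"]),
        "prescriptions": _cat(rx_rows, ["patient_id", "date", "product_code"]),
        "admissions": _cat(adm_rows, ["patient_id", "admission_date", "diagnosis_codes"]),
    }


def generate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """One-call generation: registry, truth, events, rx, admissions, rates."""
    rates = generate_reference_rates(config)
    patients, truth = generate_population(config)
    tables = generate_events(patients, truth, config, rates)
    tables["truth"] = truth
    tables["rates"] = rates
    return tables


def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete CSV fixture directory plus the ground-truth table.

    Emits the exact CSV dialects the other modules consume, the bundled
    phenotype codelist, and the smoking/flag codelists matching the
    generated events.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = generate_dataset(config)
    paths: dict[str, Path] = {}
    for name in ("patients", "events", "prescriptions", "admissions", "truth", "rates"):
        p = outdir / f"{name}.csv"
        tables[name].to_csv(p, index=False, date_format="%Y-%m-%d")
        paths[name] = p
    paths["codelist"] = outdir / "codelist.csv"
    save_codelist(example_codelist(), paths["codelist"])
    paths["smoking_codelist"] = outdir / "smoking_codelist.csv"
    smoking_codelist().to_csv(paths["smoking_codelist"], index=False)
    for name, df in flag_codelists().items():
        p = outdir / f"flag_{name}.csv"
        df.to_csv(p, index=False)
        paths[f"flag_{name}"] = p
    return paths
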