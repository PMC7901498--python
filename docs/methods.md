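# Methods

This note documents the models, conventions and design decisions behind
`opiphen`, in the order the pipeline runs.

## Phenotype definition

A patient has the phenotype when at least one dated record matches a
*definite* clinical code or an *OAT product* code from the supplied
codelist. *Probable* codes (e.g. injecting-drug-use codes that do not name
opioids, or dependence on prescribed analgesics) are excluded by default to
maximise specificity and can be switched on (`include_probable`) for
sensitivity; the matched set with the flag on is always a superset of the
default. *Excluded* codes are retained in codelists for audit but never
match. Records dated before the patient's data start still establish
history: opioid use careers are long, and a pre-registration code is
evidence of history at registration. A switch
(`require_code_in_registration`) restricts matching to in-registration
records for users who want the stricter convention.

Keyword search over terminology dictionaries supports codelist curation. A
trailing `*` is a prefix wildcard on a word stem (`misus*` matches
"misuse", "misusing"); multi-word patterns match as contiguous
case-insensitive substrings. These semantics are a design choice — keyword
lists in the field are typically published without matching rules — and
curation itself (two-reviewer screening) is out of band: the package
consumes already-categorised lists.

## Product screen

Methadone and buprenorphine products are split into OAT-specific versus
analgesic by the demographics of first prescriptions: a product is excluded
iff the fraction female exceeds 0.5, the 25th percentile of age at first
prescription is below 18 years, or the 75th percentile is above 64 years.
Comparisons are strict, so exact ties at 0.5/18/64 pass. Quartiles use
linear interpolation between order statistics (the numpy default; no
standard is fixed in the field). The rule is monotone: making a product's
demographics more "analgesic" can never rescue it. Products with fewer than
`min_n_patients` (default 1) first prescriptions are flagged for manual
review rather than auto-classified, and per-product keep/drop overrides —
modelling the final review by a prescribing professional — are applied last
and logged. Dose-based identification is deliberately not attempted: daily
doses are largely missing from these data.

## Cohort rules

* entry = max(study start, first date of good-quality data, first matching
  code); exit = min(last collection date, death date), capped at the study
  end (defaults: study window 1997-01-01 to 2018-12-31).
* eligibility: ≥1 code match, region within the configured set (the nine
  English regions by default), positive follow-up, and age 18–64 completed
  years at entry. Exclusions are tallied in the fixed order no code →
  region → no follow-up → age so counts mirror a recruitment flow chart;
  the tally plus the final size partitions the phenotype-positive set.
* birth dates: registries carry year of birth only; ages are computed
  against an imputed birthday of 1 July, which minimises the maximum
  imputation error (±6 months).
* follow-up is half-open [entry, exit). Members with entry = exit are
  excluded (zero observation time). `died` is true iff a death date exists
  and falls within follow-up; deaths registered after the end of data
  collection neither extend follow-up nor count as observed events, since
  the matching person-time is unobserved.

## Person-time and standardised mortality

Follow-up is expanded to days and accumulated in sex × single-year-of-age ×
calendar-year strata using *attained* age, so members age into older bands
(including 65+) during follow-up even though entry is capped at 64. Because
every birthday is 1 July, age and calendar year are both constant on
calendar half-years; the implementation sums interval overlaps per
half-year, which is exactly equivalent to a day-by-day loop (and is tested
cell-for-cell against one). Total stratum days are asserted equal to total
follow-up days on every run.

For decedents the death day itself contributes person-time: exit equals the
death date under the cohort rules, and the half-open interval is extended
one day so the event lands in a stratum — an event must contribute its own
risk time.

Expected deaths are E = Σ (stratum days / days in that calendar year) ×
reference rate, with 366-day leap years; every occupied stratum must have a
rate-table entry, and missing cells are a hard error listing every missing
(sex, age, year) key rather than a silent zero. The headline crude rate
divides by person-years at 365.25 days/year — the day-level definition
governs standardisation, while the crude denominator is a display
convention.

SMR = O/E with the exact (Garwood) Poisson interval from chi-square
quantiles: lower χ²(2O; α/2)/2E (0 when O = 0), upper χ²(2O+2; 1−α/2)/2E.
The bounds invert the Poisson tail probabilities exactly (tested against
direct tail sums) and are conservative: realised coverage is ≥ the nominal
95%. CMR intervals apply the same bounds to the death count. Default
α = 0.05.

To limit bias from delayed death registration (coroner-involved drug-poisoning
deaths register late), follow-up can be truncated before the mortality-linkage
cut-off. The default is calendar-month subtraction (linkage end minus
`lag_months = 6`); because month arithmetic conventions differ by a day or
two across tools, an explicit `cap_date` takes precedence when supplied.
Deaths on or after the cap fall outside the half-open interval and are
uncounted.

## Hospital cross-check

Among patients with ≥1 admission carrying an ICD-10 code starting with
"F11" in any diagnostic position (prefix semantics, so F11, F11.2 and the
undotted F110 dialect all match), the summary reports the fraction who also
hold a phenotype code, split by timing relative to the first qualifying
admission: before, within 30 days after (inclusive; a same-day code is day
0 of the post-admission window, since discharge-driven recording is the
mechanism of interest), or later. The three timing fractions partition the
coded cases. With zero hospital cases the fractions are reported as
missing, not zero.

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant to meet,
not any real patient data. Defaults (all overridable on
`SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `phenotype_prevalence` | 0.30 | positives per registry patient (fixture-rich; real registries are far lower) |
| `male_fraction_positive` | 0.69 | sex mix of positives |
| `age_median_positive` / `age_sigma_positive` | 32 y / 0.28 | lognormal age at first use at the study start |
| `entry_age_drift` | 0.35 y/calendar-year | ageing of the positive population |
| `imd_weights_positive` | (.066,.110,.159,.243,.422) | deprivation quintiles 1→5 |
| `smoking_positive` | 76/10/6/8 % | current/ex/never/no-records |
| `hazard_ratio` | 6.6 | mortality multiplier for positives |
| `hospital_sensitivity` | 0.88 | fraction of F11-admitted patients holding a phenotype record |
| `evidence_split` | 60/10/30 % | clinical-only / product-only / both among recorded positives |
| `confusable_*` | 80% female, ages ~N(62, 10) | transdermal-patch-like analgesic product |
| `rate_at_40_male/female`, `rate_log_slope` | 0.0022 / 0.0014 / 0.085 | reference rates, exponential in age |

Reference rates are smooth (log-linear in age), sex-differentiated,
constant over calendar years, and cover ages 15–95 across the study window
plus a margin, so no occupied stratum lacks a rate.

Deaths are simulated as a daily Bernoulli with p = annual rate ×
multiplier / days-in-year over each registration window — a first-order
approximation to the exponential hazard, accurate for the small rates
involved. Within each calendar half-year p is constant, so the process is
sampled exactly with one uniform draw per patient-segment through the
geometric inverse CDF; the simulation therefore uses the same age/calendar
resolution and the same 1-July birthday convention as the analysis, making
the null calibration exact: with multiplier 1, O/E is centred on 1, and
with multiplier 6.6 the pipeline recovers 6.6 within Monte-Carlo error.

All randomness derives from one seed through named substreams per table
(population, deaths, events, admissions). Identical configs give identical
tables.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: free-text and coding idiosyncrasies, practice-
level clustering and regional rate variation, realistic phenotype
prevalence, prescription duration/dose structure, calendar trends in
reference mortality, misrecorded dates, and linkage eligibility structure.
Tests on generated data demonstrate the *arithmetic and logic* of the
pipeline, not the real-world validity of any particular codelist.

## Problem sizes

The bundled checks use sizes chosen to make sampling error small relative
to the tolerances while keeping runs interactive: 200 replicates of
2000-patient cohorts for null coverage, 40 replicates for hazard-ratio
recovery, ~2000 first prescriptions for the product screen, and ~5000
hospital cases for the sensitivity recovery. Demographic concentration
checks use 20,000 patients (1-percentage-point tolerance on a 69% share).

## Known limitations

* The bundled codelist is illustrative; real analyses must supply curated
  Read/SNOMED/product lists in the documented CSV format.
* One death date per patient; no reconciliation between primary-care and
  national death registration sources.
* No cause-specific mortality or competing-risks analysis.
* Linked-subset analyses are supported only by filtering the input registry
  to linkage-eligible patients before building the cohort.
* Expected deaths printed at 1 d.p. cannot always reproduce a published SMR
  at 2 d.p.; replay checks accept only rows where the rounding permits.
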