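"""Lexis expansion, expected deaths, exact Poisson SMR/CMR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import opiphen as op

from conftest import make_members


T = pd.Timestamp


def expand_daily(members):
    """Independent day-by-day oracle for the person-time expansion."""
    cells = {}
    for row in members.itertuples(index=False):
        end = row.exit
        if row.died and pd.notna(row.death_date) and row.death_date >= row.exit:
            end = row.death_date + pd.Timedelta(days=1)
        day = row.entry
        while day < end:
            age = day.year - row.year_of_birth - ((day.month, day.day) < (7, 1))
            cell = cells.setdefault((row.sex, age, day.year), [0, 0])
            cell[0] += 1
            day += pd.Timedelta(days=1)
        if row.died:
            d = row.death_date
            age = d.year - row.year_of_birth - ((d.month, d.day) < (7, 1))
            cells.setdefault((row.sex, age, d.year), [0, 0])[1] += 1
    return pd.DataFrame(
        [
            {"sex": s, "age": a, "year": y, "days": v[0], "observed_deaths": v[1]}
            for (s, a, y), v in sorted(cells.items())
        ]
    )


def random_members(rng, n):
    """Members spanning birthdays, year ends and leap years."""
    rows = []
    for i in range(n):
        entry = T("1998-01-01") + pd.Timedelta(days=int(rng.integers(0, 9 * 365)))
        exit_ = entry + pd.Timedelta(days=int(rng.integers(1, 1500)))
        died = bool(rng.random() < 0.3)
        rows.append(
            {
                "patient_id": f"r{i}",
                "sex": "M" if rng.random() < 0.5 else "F",
                "year_of_birth": int(rng.integers(1950, 1981)),
                "entry": entry,
                "exit": exit_,
                "age_at_entry": 0,
                "died": died,
                "death_date": exit_ if died else None,
            }
        )
    m = make_members(rows)
    birth = pd.to_datetime({"year": m["year_of_birth"], "month": 7, "day": 1})
    m["age_at_entry"] = (
        m["entry"].dt.year - m["year_of_birth"]
        - ((m["entry"].dt.month * 100 + m["entry"].dt.day) < 701).astype(int)
    )
    return m


class TestTruncation:
    def members(self):
        return make_members(
            [
                {"patient_id": "a", "entry": "2015-01-01", "exit": "2019-04-01",
                 "died": True, "death_date": "2019-04-01"},
                {"patient_id": "b", "entry": "2015-01-01", "exit": "2017-06-01"},
                {"patient_id": "c", "entry": "2018-12-01", "exit": "2019-02-01"},
            ]
        )

    def test_month_subtraction_default(self):
        out = op.truncate_for_registration_lag(self.members(), linkage_end="2019-05-01")
        assert out["exit"].max() == T("2018-11-01")

    def test_explicit_cap_date_takes_precedence(self):
        out = op.truncate_for_registration_lag(
            self.members(), linkage_end="2019-05-01", cap_date="2018-10-30"
        )
        assert out["exit"].max() == T("2018-10-30")

    def test_exit_before_cap_unchanged_and_short_members_dropped(self):
        out = op.truncate_for_registration_lag(self.members(), cap_date="2018-10-30")
        kept = out.set_index("patient_id")
        assert kept.loc["b", "exit"] == T("2017-06-01")
        assert "c" not in kept.index  # entry after the cap: no follow-up left

    def test_death_on_cap_date_is_uncounted(self):
        members = make_members(
            [{"patient_id": "a", "entry": "2018-01-01", "exit": "2018-10-30",
              "died": True, "death_date": "2018-10-30"}]
        )
        out = op.truncate_for_registration_lag(members, cap_date="2018-10-30")
        assert not out["died"].any()
        strata = op.expand_person_time(out)
        assert strata["observed_deaths"].sum() == 0
        # half-open interval: the cap day itself contributes no person-time
        assert strata["days"].sum() == (T("2018-10-30") - T("2018-01-01")).days


class TestExpansion:
    def test_short_interval_single_cell(self):
        m = make_members(
            [{"patient_id": "a", "entry": "2000-03-01", "exit": "2000-03-11",
              "age_at_entry": 29}]
        )
        strata = op.expand_person_time(m)
        assert len(strata) == 1
        row = strata.iloc[0]
        assert (row["days"], row["age"], row["year"]) == (10, 29, 2000)

    def test_year_boundary_split_conserves_days(self):
        m = make_members(
            [{"patient_id": "a", "entry": "2000-12-01", "exit": "2001-02-01"}]
        )
        strata = op.expand_person_time(m)
        assert set(strata["year"]) == {2000, 2001}
        assert strata["days"].sum() == 62

    def test_birthday_split_matches_daily_oracle(self):
        m = make_members(
            [{"patient_id": "a", "year_of_birth": 1970,
              "entry": "2000-06-01", "exit": "2000-08-01"}]
        )
        strata = op.expand_person_time(m)
        by_age = strata.set_index("age")["days"]
        assert by_age.to_dict() == {29: 30, 30: 31}  # age steps on 1 July
        pd.testing.assert_frame_equal(
            strata, expand_daily(m), check_dtype=False
        )

    def test_oracle_equivalence_on_random_members(self):
        """Cell-for-cell agreement with a naive day-by-day loop on 100
        random members spanning birthdays, year ends and leap years."""
        m = random_members(np.random.default_rng(12345), 100)
        fast = op.expand_person_time(m)
        slow = expand_daily(m)
        pd.testing.assert_frame_equal(
            fast.reset_index(drop=True), slow.reset_index(drop=True), check_dtype=False
        )
        # conservation, including the extra death day for decedents
        follow = (m["exit"] - m["entry"]).dt.days.sum() + m["died"].sum()
        assert fast["days"].sum() == follow

    def test_death_day_lands_in_a_stratum(self):
        m = make_members(
            [{"patient_id": "a", "entry": "2004-01-01", "exit": "2004-06-30",
              "died": True, "death_date": "2004-06-30"}]
        )
        strata = op.expand_person_time(m)
        assert strata["observed_deaths"].sum() == 1
        assert strata["days"].sum() == 181 + 1  # decedent contributes the death day

    def test_nonpositive_followup_is_error(self):
        m = make_members(
            [{"patient_id": "a", "entry": "2004-01-01", "exit": "2004-01-01"}]
        )
        with pytest.raises(ValueError, match="filtered"):
            op.expand_person_time(m)


class TestExpectedDeaths:
    def rates(self, rate=0.01):
        grid = [
            {"sex": s, "age": a, "year": y, "rate": rate}
            for s in ("M", "F") for a in range(18, 90) for y in (2003, 2004, 2005)
        ]
        return pd.DataFrame(grid)

    def strata(self, rows):
        return pd.DataFrame(rows, columns=["sex", "age", "year", "days", "observed_deaths"])

    def test_full_nonleap_year_at_rate(self):
        s = self.strata([("M", 30, 2003, 365, 0)])
        assert op.expected_deaths(s, self.rates(0.01)) == pytest.approx(0.01)

    def test_zero_rates_give_zero(self):
        s = self.strata([("M", 30, 2003, 365, 0), ("F", 40, 2005, 100, 1)])
        assert op.expected_deaths(s, self.rates(0.0)) == 0.0

    def test_leap_year_hand_arithmetic(self):
        # 366 days of 2004 at 0.02 plus 182 days of 2005 at 0.01
        rates = pd.concat(
            [
                self.rates(0.02).query("year == 2004"),
                self.rates(0.01).query("year == 2005"),
            ]
        )
        s = self.strata([("M", 30, 2004, 366, 0), ("M", 31, 2005, 182, 0)])
        assert op.expected_deaths(s, rates) == pytest.approx(0.02 + 182 / 365 * 0.01)

    def test_missing_cells_error_lists_keys(self):
        s = self.strata([("M", 30, 1990, 100, 0), ("F", 40, 1991, 50, 0)])
        with pytest.raises(ValueError) as err:
            op.expected_deaths(s, self.rates())
        assert "('M', 30, 1990)" in str(err.value)
        assert "('F', 40, 1991)" in str(err.value)

    def test_empty_strata_do_not_need_rates(self):
        s = self.strata([("M", 30, 1990, 0, 0)])
        assert op.expected_deaths(s, self.rates()) == 0.0


class TestSMR:
    def test_equal_observed_expected_is_one(self):
        assert op.smr(7, 7.0).smr == pytest.approx(1.0)

    def test_exact_poisson_ci_example(self):
        res = op.smr(5, 2.0)
        assert res.smr == pytest.approx(2.5)
        assert res.ci_low == pytest.approx(0.8117, abs=1e-4)
        assert res.ci_high == pytest.approx(5.8342, abs=1e-4)

    def test_zero_observed_has_zero_lower_bound(self):
        res = op.smr(0, 3.0)
        assert res.smr == 0.0 and res.ci_low == 0.0 and res.ci_high > 0

    def test_bounds_bracket_estimate(self):
        res = op.smr(12, 5.0)
        assert res.ci_low <= res.smr <= res.ci_high

    def test_ci_matches_poisson_tail_probabilities(self):
        """Dual route: chi-square quantile bounds invert the Poisson tails
        (P(X >= O | mu=lower) = alpha/2 and P(X <= O | mu=upper) = alpha/2)."""
        for o in (1, 5, 20, 150):
            res = op.smr(o, 1.0)
            assert poisson.sf(o - 1, res.ci_low) == pytest.approx(0.025, abs=1e-9)
            assert poisson.cdf(o, res.ci_high) == pytest.approx(0.025, abs=1e-9)

    def test_monotone_in_observed_and_relative_width_shrinks(self):
        smrs = [op.smr(o, 10.0) for o in (5, 10, 50, 200)]
        values = [r.smr for r in smrs]
        assert values == sorted(values) and len(set(values)) == len(values)
        rel_width = [(r.ci_high - r.ci_low) / r.smr for r in smrs]
        assert rel_width == sorted(rel_width, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            op.smr(3, 0.0)
        with pytest.raises(ValueError):
            op.smr(-1, 2.0)


class TestCrudeRate:
    def test_simple_rate(self):
        res = op.crude_rate_from_person_years(10, 1000.0)
        assert res.rate_per_1000 == pytest.approx(10.0)
        lo, hi = op.smr(10, 1.0).ci_low, op.smr(10, 1.0).ci_high
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_zero_deaths(self):
        res = op.crude_rate_from_person_years(0, 50.0)
        assert res.rate_per_1000 == 0.0 and res.ci_low == 0.0

    def test_person_day_conversion(self):
        res = op.crude_rate(10, 365250)  # exactly 1000 person-years
        assert res.person_years == pytest.approx(1000.0)
        assert res.rate_per_1000 == pytest.approx(10.0)

    def test_zero_person_time_is_error(self):
        with pytest.raises(ValueError):
            op.crude_rate(1, 0)


class TestSMRTable:
    def test_single_member(self, synth):
        m = make_members(
            [{"patient_id": "a", "year_of_birth": 1970,
              "entry": "2000-07-01", "exit": "2005-07-01", "age_at_entry": 30}]
        )
        table = op.smr_table(m, synth["rates"])
        nonzero = table[(table["sex"] == "M") & (table["age_band"] == "30-39")]
        assert len(nonzero) == 1
        all_ages = table[(table["sex"] == "M") & (table["age_band"] == "All ages")].iloc[0]
        assert all_ages["follow_up_years"] == pytest.approx(nonzero.iloc[0]["follow_up_years"])

    def test_band_rows_aggregate_to_all_ages(self, synth, synth_cohort):
        members, _ = synth_cohort
        table = op.smr_table(members, synth["rates"])
        for sex in ("F", "M", "Both"):
            sub = table[table["sex"] == sex]
            bands = sub[sub["age_band"] != "All ages"]
            total = sub[sub["age_band"] == "All ages"].iloc[0]
            assert bands["observed"].sum() == total["observed"]
            assert bands["expected"].sum() == pytest.approx(total["expected"])
            assert bands["follow_up_years"].sum() == pytest.approx(total["follow_up_years"])
        both = table[table["sex"] == "Both"]
        fm = table[table["sex"].isin(["F", "M"]) & (table["age_band"] == "All ages")]
        assert both[both["age_band"] == "All ages"]["observed"].iloc[0] == fm["observed"].sum()

    def test_members_age_into_older_bands(self, synth, synth_cohort):
        """Attained-age stratification: entry is capped at 64 but long
        follow-up produces person-time in the 65+ band."""
        members, _ = synth_cohort
        table = op.smr_table(members, synth["rates"])
        old = table[(table["sex"] == "Both") & (table["age_band"] == "65+")]
        assert len(old) == 1 and old.iloc[0]["follow_up_years"] > 0
        assert pd.isna(old.iloc[0]["n_baseline"])
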