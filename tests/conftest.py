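import pandas as pd
import pytest

import opiphen as op


@pytest.fixture(scope="session")
def codelist():
    return op.example_codelist()


@pytest.fixture(scope="session")
def synth():
    """A mid-sized synthetic dataset shared by read-only tests."""
    cfg = op.SimulationConfig(seed=20, n_patients=4000)
    tables = op.generate_dataset(cfg)
    tables["config"] = cfg
    return tables


@pytest.fixture(scope="session")
def synth_cohort(synth, codelist):
    members, tally = op.build_cohort(
        synth["patients"], synth["events"], synth["prescriptions"], codelist
    )
    return members, tally


def make_patients(rows):
    """Registry builder for hand-constructed fixtures.

    ``rows``: dicts with patient_id and any overrides of the defaults.
    """
    defaults = {
        "sex": "M",
        "year_of_birth": 1970,
        "region": "London",
        "imd_quintile": 5,
        "data_start": "1997-01-01",
        "data_end": "2018-12-31",
        "death_date": None,
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    for col in ("data_start", "data_end", "death_date"):
        out[col] = pd.to_datetime(out[col])
    return out


def make_events(rows):
    out = pd.DataFrame(rows, columns=["patient_id", "date", "code_id", "terminology"])
    out["date"] = pd.to_datetime(out["date"])
    return out


def make_prescriptions(rows):
    out = pd.DataFrame(rows, columns=["patient_id", "date", "product_code"])
    out["date"] = pd.to_datetime(out["date"])
    return out


def make_members(rows):
    """Cohort-member builder (entry/exit/died ready for person-time)."""
    defaults = {
        "sex": "M",
        "year_of_birth": 1970,
        "index_code_date": "2000-01-01",
        "age_at_entry": 30,
        "died": False,
        "death_date": None,
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    for col in ("entry", "exit", "index_code_date", "death_date"):
        out[col] = pd.to_datetime(out[col])
    return out
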