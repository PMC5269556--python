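import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mdclaims.synthetic import SyntheticConfig, generate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_claims(rows):
    """rows: (person_id, date, code, setting, specialty, source) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["person_id", "service_date", "icd9_code", "setting", "provider_specialty", "source"],
    )
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def make_rx(rows):
    df = pd.DataFrame(rows, columns=["person_id", "fill_date", "drug_name"])
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    return df


def make_demo(rows):
    df = pd.DataFrame(rows, columns=["person_id", "sex", "race", "birth_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


def make_gold(rows):
    return pd.DataFrame(rows, columns=["person_id", "reviewed", "confirmed", "md_type"])


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,500-person synthetic dual-surveillance cohort (fixed seed)."""
    return generate(SyntheticConfig(n_persons=2500), seed=7)


@pytest.fixture(scope="session")
def small_universe(small_cohort):
    return set(small_cohort.claims["person_id"]) & set(small_cohort.gold["person_id"])
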