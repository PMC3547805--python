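from datetime import date

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cohortbridge.reporting import RunConfig, run_pipeline
from cohortbridge.studies import default_study_config
from cohortbridge.synthpop import generate_study

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A small two-wave study shared by linkage/lexis/reporting tests."""
    cfg = default_study_config(seed=11, n_persons=6000)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """A full pipeline run on a small study (no hazards stage)."""
    cfg = RunConfig(study=default_study_config(seed=11, n_persons=6000),
                    run_hazards=False)
    return run_pipeline(cfg)


def tiny_census(rows) -> pd.DataFrame:
    """Hand-built census table from (person_id, sex, birth, canton,
    nationality, marital) tuples; other attributes fixed."""
    from cohortbridge.geography import CANTON_TO_REGION

    df = pd.DataFrame(rows, columns=["person_id", "sex", "birth_date",
                                     "canton", "nationality", "marital_status"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["region"] = df["canton"].map(CANTON_TO_REGION)
    df["education"] = "secondary"
    df["religion"] = "protestant"
    df["urbanization"] = "urban"
    df["household"] = "multi"
    return df


def tiny_registry(rows) -> pd.DataFrame:
    """Hand-built registry from (certificate_id, sex, birth, canton,
    nationality, marital, death, cause, linked, person_id) tuples."""
    from cohortbridge.geography import CANTON_TO_REGION

    df = pd.DataFrame(rows, columns=["certificate_id", "sex", "birth_date",
                                     "canton", "nationality", "marital_status",
                                     "death_date", "official_cause", "linked",
                                     "person_id"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    df["region"] = df["canton"].map(CANTON_TO_REGION)
    df["person_id"] = df["person_id"].astype("Int64")
    df["linked"] = df["linked"].astype(bool)
    return df
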