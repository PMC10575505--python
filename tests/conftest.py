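import pandas as pd
import pytest

from capqual.config import CodeConfig, SimConfig
from capqual.guidelines import default_rules
from capqual.synthetic import generate_claims, generate_cohort


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def code_config():
    return CodeConfig()


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """1000-patient dataset with all deliberate edge cases off."""
    config = SimConfig.noiseless(n_patients=1000, seed=42)
    registry = generate_cohort(config)
    visits, dispensations, admissions, truth = generate_claims(config, registry)
    return config, registry, visits, dispensations, admissions, truth


@pytest.fixture(scope="session")
def small_default_dataset():
    """800-patient dataset with decoys, chronic/hospitalized episodes and LTC."""
    config = SimConfig(n_patients=800, seed=7)
    registry = generate_cohort(config)
    visits, dispensations, admissions, truth = generate_claims(config, registry)
    return config, registry, visits, dispensations, admissions, truth


def make_visits(days, patient_id="P1", code="481", system="ICD9"):
    """Visit table from day offsets (days since 2014-01-01)."""
    epoch = pd.Timestamp("2014-01-01")
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "service_date": [(epoch + pd.Timedelta(days=int(d))).strftime("%Y-%m-%d")
                             for d in days],
            "diagnostic_code": code,
            "code_system": system,
            "provider_type": "GP",
        }
    )
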