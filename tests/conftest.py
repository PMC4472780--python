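import pytest

from vacod.causes import AgeGroup
from vacod.synthetic_cohort import default_config, generate_cohort
from vacod.va_data import FLAG_FIELDS, SymptomProfile, VARecord


def child_record(record_id="r1", site="Kampala", age_days=365, **profile_kwargs):
    return VARecord(record_id, site, age_days, SymptomProfile.all_no(**profile_kwargs))


def neonate_record(record_id="n1", site="Kampala", age_days=5, **profile_kwargs):
    return VARecord(record_id, site, age_days, SymptomProfile.all_no(**profile_kwargs))


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-shaped cohort (3 sites, 104 neonates + 615 children)."""
    config = default_config(seed=7)
    return config, generate_cohort(config, seed=7)
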