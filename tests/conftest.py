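import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

import opioidtraj as ot


@pytest.fixture(scope="session")
def small_config():
    return ot.SimConfig(
        seed=42,
        n_regions=2,
        practices_per_region=3,
        prescribers_per_practice=3,
        patients_per_prescriber=20,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return ot.simulate_study(small_config)


@pytest.fixture(scope="session")
def conversion_table():
    return ot.ConversionTable.default()


@pytest.fixture(scope="session")
def small_clean(small_study, conversion_table):
    clean, log = ot.clean_prescriptions(small_study.therapy, conversion=conversion_table)
    return ot.add_mme(clean, conversion_table), log


@pytest.fixture(scope="session")
def small_cohort(small_study, small_clean):
    clean, _ = small_clean
    cfg = small_study.config
    cohort, excl = ot.derive_new_users(
        small_study.population.patient, clean, small_study.conditions, cfg.study_start, cfg.study_end
    )
    cohort = ot.derive_covariates(cohort, small_study.conditions, small_study.population.patient)
    return cohort, excl
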