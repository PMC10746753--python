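import numpy as np
import pytest

from transpkpd import builtin_tables, species_table
from transpkpd.synth import generate_study, study_design


@pytest.fixture(scope="session")
def tables():
    return builtin_tables()


@pytest.fixture(scope="session")
def species_records(tables):
    return tables[0]


@pytest.fixture(scope="session")
def human_record():
    return species_table("human")


@pytest.fixture(scope="session")
def mouse_pk(tables):
    return tables[1]


@pytest.fixture(scope="session")
def mouse_pd(tables):
    return tables[2]


@pytest.fixture(scope="session")
def noisefree_studies(mouse_pk, mouse_pd):
    """PK/PD-01 + PK/PD-02 generated without observation noise."""
    s1 = generate_study(study_design("PKPD-01"), mouse_pk, mouse_pd, noise_cv=0.0, seed=11)
    s2 = generate_study(study_design("PKPD-02"), mouse_pk, mouse_pd, noise_cv=0.0, seed=12)
    return s1, s2


@pytest.fixture(scope="session")
def noisy_studies(mouse_pk, mouse_pd):
    """PK/PD-01 + PK/PD-02 with the default 20% CV observation noise."""
    s1 = generate_study(study_design("PKPD-01"), mouse_pk, mouse_pd, noise_cv=0.2, seed=21)
    s2 = generate_study(study_design("PKPD-02"), mouse_pk, mouse_pd, noise_cv=0.2, seed=22)
    return s1, s2
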