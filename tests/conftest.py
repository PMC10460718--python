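import numpy as np
import pytest

from pkpdkit.cohort import CohortSpec, simulate_pk_dataset
from pkpdkit.pd_model import PDParams, PopulationPDModel, final_pd_model
from pkpdkit.pk_model import PKParams, PopulationPKModel, final_pk_model


@pytest.fixture(scope="session")
def pk_final():
    return final_pk_model()


@pytest.fixture(scope="session")
def pd_final():
    return final_pd_model()


@pytest.fixture(scope="session")
def pk_base(pk_final):
    """Final-model structural parameters and variabilities, no covariate effects."""
    return PopulationPKModel(
        thetas=PKParams(0.755, 19.1, 1.41, 0.184, 0.156, 1.0),
        covariate_effects=[],
        omega2=dict(pk_final.omega2),
        sigma_serial=0.319,
        sigma_sparse=0.543,
    )


@pytest.fixture(scope="session")
def pd_base(pd_final):
    return PopulationPDModel(
        thetas=PDParams(0.350, 3.17, 143.0, 85.8),
        covariate_effects=[],
        omega2=dict(pd_final.omega2),
        sigma_prop=0.153,
        sigma_add=3.94,
    )


@pytest.fixture(scope="session")
def serial_table(pk_base):
    """Small single-dose serial-sampling PK dataset with known truth."""
    spec = CohortSpec(n_subjects=24, duration_days=1, design="serial",
                      noncompliant_fraction=0.0, seed=42)
    table, truth = simulate_pk_dataset(spec, pk_base)
    return table, truth
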