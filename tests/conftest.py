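import pytest

import tamsim as ts


@pytest.fixture(scope="session")
def bundled_tables():
    return ts.load_bundled_frequency_tables()


@pytest.fixture(scope="session")
def params():
    return ts.placeholder_parameters()


@pytest.fixture(scope="session")
def small_pool():
    return ts.generate_covariate_pool(ts.CovariatePoolSpec(n=400, seed=7))


@pytest.fixture(scope="session")
def default_pool():
    return ts.generate_covariate_pool(ts.CovariatePoolSpec(seed=7))


@pytest.fixture()
def reference_patient():
    """Typical individual: AS 2, reference covariates, zero random effects."""
    return ts.VirtualPatient(
        patient_id=0, group="European", activity_score="2",
        age=55.0, weight=67.0, eta_cl20=0.0, eta_cl23=0.0,
    )


@pytest.fixture()
def regimen():
    return ts.DosingRegimen(dose=20.0, tau=24.0, duration=182.0)
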