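import pytest

from neoprofiler import (CallerParams, NeoantigenParams, SimulationParams,
                         ToyBindingModel, generate_reference, simulate_cohort)


@pytest.fixture(scope="session")
def toy_model():
    return ToyBindingModel()


@pytest.fixture(scope="session")
def reference_panel():
    """A small deterministic transcript panel shared across tests."""
    return generate_reference(20, (300, 900), seed=101)


@pytest.fixture(scope="session")
def small_cohort(reference_panel):
    """Five-patient cohort at default depths, fixed seed."""
    params = SimulationParams(n_patients=5, tnbc_fraction=0.4,
                              mean_burden=40.0, seed=202)
    return simulate_cohort(reference_panel, params)


@pytest.fixture
def default_caller_params():
    return CallerParams()


@pytest.fixture
def default_neo_params():
    return NeoantigenParams()
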