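import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from donorcalc.design import DesignMatrix
from donorcalc.reference import reference_model, reference_spec
from donorcalc.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def ref_spec():
    return reference_spec()


@pytest.fixture(scope="session")
def cohort737():
    """One synthetic cohort at the study size, shared across tests."""
    return generate_cohort(GeneratorConfig(n=737, seed=20))


@pytest.fixture(scope="session")
def fitted737(cohort737, ref_spec):
    from donorcalc import build_design_matrix, fit_weibull_aft
    fit = fit_weibull_aft(build_design_matrix(cohort737, ref_spec))
    assert fit.converged
    return fit


def toy_design(seed=0, n=20, p=2, censor_frac=0.4):
    """Small random design with positive times for likelihood tests."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    times = rng.gamma(2.0, 200.0, size=n) + 1.0
    events = rng.uniform(size=n) > censor_frac
    if not events.any():
        events[0] = True
    cols = ["Intercept"] + [f"x{i}" for i in range(1, p)]
    return DesignMatrix(cols, X, times, events)
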