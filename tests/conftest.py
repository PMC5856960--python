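import numpy as np
import pytest

from caaflow import circulation
from caaflow.pipeline import RunConfig, run_cohort


@pytest.fixture(scope="session")
def targets():
    """A fixed adult-scale patient used across the circulation tests."""
    return circulation.ClinicalTargets(
        heart_rate=75.0,
        systolic_pressure=120.0,
        diastolic_pressure=80.0,
        stroke_volume=70.0,
        body_surface_area=1.8,
        coronary_flow_fraction=0.04,
    )


@pytest.fixture(scope="session")
def tuned_params(targets):
    return circulation.tune(targets)


@pytest.fixture(scope="session")
def tuned_waveforms(targets, tuned_params):
    return circulation.simulate(tuned_params, targets.heart_rate)


@pytest.fixture(scope="session")
def cohort_result():
    """One full built-in cohort run shared by pipeline and acceptance tests."""
    return run_cohort(RunConfig(cohort="table1", seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
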