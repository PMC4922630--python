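import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nettrans import (
    SurveyDesignSpec,
    fit_prevalence,
    make_truth,
    sample_cross_section,
    toy_growth_reference,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_early():
    return make_truth("early_peak")


@pytest.fixture(scope="session")
def toy_ref():
    return toy_growth_reference()


@pytest.fixture(scope="session")
def classified_sample(truth_early):
    """Mid-sized classified cross-section reused by the estimation tests."""
    return sample_cross_section(
        truth_early, SurveyDesignSpec(n_per_cycle=20_000), cycle="fix",
        seed=314, emit_anthropometry=False,
    )


@pytest.fixture(scope="session")
def fitted_curve(classified_sample):
    return fit_prevalence(classified_sample, stratum="fixture")


def random_prob_pair(rng):
    return rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
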