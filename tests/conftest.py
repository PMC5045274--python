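import numpy as np
import pytest
from hypothesis import settings

import epvsim as e

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def generator() -> e.GeneratorConfig:
    """Calibrated 12-predictor generator shared across the suite."""
    cfg = e.GeneratorConfig(predictors=e.default_thin_spec(), seed=1)
    return e.calibrated_config(cfg, rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def dev_cohort(generator) -> e.Cohort:
    """200k-person synthetic development cohort (~9k events)."""
    return e.generate_cohort(generator, 200_000, np.random.default_rng(2))


@pytest.fixture(scope="session")
def truths(generator) -> dict[str, float]:
    return e.true_coef_map(generator.predictors)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def five_subject_cohort() -> e.Cohort:
    """Tiny fixture used against brute-force oracles."""
    return e.Cohort(
        covariates=np.array([[1.0], [0.0], [1.0], [0.0], [1.0]]),
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        event=np.array([1, 1, 0, 1, 0]),
        names=["x"],
    )
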