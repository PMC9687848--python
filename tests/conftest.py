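import numpy as np
import pytest
from hypothesis import settings

import xcsr_extubation as xe

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema():
    return xe.default_schema()


@pytest.fixture(scope="session")
def planted2_cohort():
    """Noiseless 228-record cohort labelled by a 2-variable interval rule."""
    rule = xe.default_planted_rule(["m1_VE", "m30_VE"])
    cfg = xe.GeneratorConfig(
        seed=1, n_total=228, n_missing_records=0
    ).with_rule(rule)
    return xe.generate(cfg), rule


@pytest.fixture(scope="session")
def planted2_normalized(planted2_cohort):
    cohort, _ = planted2_cohort
    norm, ranges = xe.normalize(cohort.features)
    return norm.to_numpy(float), cohort.outcomes, ranges


@pytest.fixture(scope="session")
def short_trained(planted2_normalized):
    """A cheap trained model for structural checks (10 epochs)."""
    X, y, _ = planted2_normalized
    params = xe.XCSRParams(epochs=10, seed=1)
    return xe.train(X, y, params), params, X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
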