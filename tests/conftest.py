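import numpy as np
import pytest

from terrapin.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_deployment():
    """A 2-individual, 4-day labelled deployment shared across tests."""
    return generate(GeneratorConfig(n_individuals=2, n_days=4), seed=7)


@pytest.fixture(scope="session")
def small_evaluation(small_deployment):
    from terrapin.evaluation import evaluate_deployment

    return evaluate_deployment(dep=small_deployment)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
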