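import numpy as np
import pytest

from bayeshte.models import ModelSpec
from bayeshte.synthetic import GeneratorConfig, generate_trial


@pytest.fixture(scope="session")
def fast_spec():
    """Reduced sampler budget for unit tests: 2 chains, short warm-up."""
    return ModelSpec(chains=2, warmup=200, draws=300, seed=101)


@pytest.fixture(scope="session")
def matched_cohort():
    """A cohort whose generative model coincides with the primary analysis
    model (site intercepts + copd/haem effects only), true log-OR 0.3."""
    cfg = GeneratorConfig(
        n_patients=2000, n_sites=10, treatment_log_or=0.3,
        covariate_log_ors={"copd": 0.2, "haem": 0.4},
        baseline_logit=-0.3, missing_rates={}, seed=424)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default cohort emulation (with its usual low missingness)."""
    return generate_trial(GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
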