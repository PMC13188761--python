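import numpy as np
import pytest
from hypothesis import settings

from piedpiper import synthetic
from piedpiper.ssm import FitOptions

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Compact study: 4 night chains of 80 analysis days, two pulsed releases."""
    return synthetic.SyntheticConfig(n_years=4, rng_seed=11)


@pytest.fixture(scope="session")
def model_panels(small_config):
    """Chains with realistic covariates and model-scale responses."""
    panels, truth = synthetic.make_model_panels(
        small_config, covariate_names=("hatchery_diff", "flow_diff", "season")
    )
    return panels, truth


@pytest.fixture(scope="session")
def count_dataset(small_config):
    """Full count-level synthetic dataset (trap records, env, truth)."""
    return synthetic.generate_dataset(small_config)


@pytest.fixture()
def fast_options():
    return FitOptions(n_starts=2, compute_ci=False)
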