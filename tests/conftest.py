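import dataclasses

import pytest

from springlayer.models import ModelSpec, fit_combined
from springlayer.preprocess import build_feature_table
from springlayer.synthetic import GeneratorConfig, generate_study

SMALL_SITES = ("LA_A", "LL_P", "UA_A", "UL_P")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A quick-to-generate study: 12 subjects at 4 sites, short traces."""
    return GeneratorConfig(
        n_subjects=12, sites=SMALL_SITES, n_trace_points=20, seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    trials, truth = generate_study(small_config)
    return trials, truth


@pytest.fixture(scope="session")
def small_features(small_study):
    trials, _ = small_study
    return build_feature_table(trials)


@pytest.fixture(scope="session")
def noise_free_config() -> GeneratorConfig:
    """All random-effect, residual and measurement noise switched off."""
    return GeneratorConfig(
        n_subjects=20,
        sigma_subject=0.0,
        sigma_location=0.0,
        sigma_resid=0.0,
        trace_noise_sd=0.0,
        deformation_noise_sd=0.0,
        n_trace_points=25,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    trials, truth = generate_study(noise_free_config)
    return trials, truth


@pytest.fixture(scope="session")
def noise_free_features(noise_free_study):
    trials, _ = noise_free_study
    return build_feature_table(trials)


@pytest.fixture(scope="session")
def combined_physics_fit(small_features):
    return fit_combined(small_features, ModelSpec("physics", "combined"))


def replace(config, **kwargs) -> GeneratorConfig:
    return dataclasses.replace(config, **kwargs)
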