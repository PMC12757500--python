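import dataclasses

import pytest

from ckdfair import GeneratorConfig, MlpConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator configuration for fast module tests."""
    return dataclasses.replace(
        GeneratorConfig(), n_total=600, biomarker_subset_size=120, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def fast_mlp_config():
    """Training configuration with a reduced epoch budget for unit tests."""
    return dataclasses.replace(MlpConfig(), max_epochs=30, early_stopping_patience=5)
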