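import numpy as np
import pytest

from gscnet import (
    CohortConfig,
    ModelConfig,
    RenderConfig,
    build_model,
    generate_cohort,
)


def tiny_model_config(**overrides) -> ModelConfig:
    """A 32px, narrow configuration that keeps unit tests fast."""
    base = dict(
        input_size=32,
        branch_channels=16,
        fusion_channels=16,
        se_reduction=4,
        sc_conv_channels=(16, 8),
        sc_fc_widths=(8, 8),
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(tiny_model_config(), seed=0)


@pytest.fixture(scope="session")
def tiny_render():
    return RenderConfig(image_size=32)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_render):
    """12 patients, 32px images, in memory."""
    return generate_cohort(CohortConfig(n_patients=12, seed=7), tiny_render)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
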