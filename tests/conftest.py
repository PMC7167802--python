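import numpy as np
import pytest

from sdunet.architectures import ModelConfig, build_variant
from sdunet.nn import Model
from sdunet.synthetic_data import generate_em_like


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest buildable config: 16x16 input, base 2, instance-norm groups."""
    return ModelConfig(input_height=16, input_width=16, input_channels=1,
                       base_filters=2, num_groups=2, seed=3)


@pytest.fixture(scope="session")
def em_samples():
    return generate_em_like(4, 32, 32, seed=11)


def make_model(variant="sd_unet", **overrides) -> Model:
    defaults = dict(input_height=16, input_width=16, input_channels=1,
                    base_filters=2, num_groups=2, seed=3, variant=variant)
    defaults.update(overrides)
    cfg = ModelConfig(**defaults)
    return Model(build_variant(variant, cfg))
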