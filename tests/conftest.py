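import numpy as np
import pytest

from neurofuse import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """Small config with dropout and positional encoding off (deterministic
    symmetric behavior for the oracle/equivalence tests)."""
    return ModelConfig(
        d=3,
        h=2,
        w=2,
        c=1,
        h_v=4,
        d_h=4,
        d_f=3,
        n_classes=2,
        conv_kernel=3,
        dropout_p=0.0,
        use_positional_encoding=False,
        max_time=16,
    )


def random_model_config(rng: np.random.Generator) -> ModelConfig:
    return ModelConfig(
        d=int(rng.integers(1, 5)),
        h=int(rng.integers(1, 4)),
        w=int(rng.integers(1, 4)),
        c=int(rng.integers(1, 3)),
        h_v=int(rng.integers(2, 6)),
        d_h=int(rng.integers(2, 6)),
        d_f=int(rng.integers(2, 6)),
        n_classes=int(rng.integers(2, 5)),
        conv_kernel=int(rng.choice([1, 3, 5])),
        dropout_p=float(rng.uniform(0, 0.6)),
        use_positional_encoding=bool(rng.integers(0, 2)),
        max_time=32,
    )
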