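import numpy as np
import pytest

from pupanet import (SyntheticConfig, TrainConfig, generate_image_set,
                     prepare_set, train)


@pytest.fixture(scope="session")
def small_set():
    """Separable 5-group synthetic set (6 specimens/group, delta=2)."""
    cfg = SyntheticConfig(n_groups=5, per_group=6, effect_size=2.0, seed=11)
    images, manifest = generate_image_set(cfg)
    return prepare_set(images), manifest


@pytest.fixture(scope="session")
def small_model(small_set):
    """Contrast network trained on the small separable set (tiny budget)."""
    prepped, manifest = small_set
    cfg = TrainConfig(n_rounds=2, pairs_per_round=1600, lr=3e-3, balanced=True,
                      init_seed=1, shuffle_seed=2)
    return train(prepped, manifest, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
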