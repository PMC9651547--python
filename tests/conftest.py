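import numpy as np
import pytest

from htem.datakit import SplitSpec, SynthSpec, generate_synthetic_dataset, split_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 classes x 8 images at 32 px, split 37.5/25/37.5 — smallest end-to-end set."""
    ds = generate_synthetic_dataset(SynthSpec(n_classes=2, per_class=8,
                                              image_size=32, seed=7))
    return split_dataset(ds, SplitSpec(seed=7))


@pytest.fixture(scope="session")
def small_multiclass_dataset():
    """4 classes x 10 images at 32 px for protocol-level tests."""
    ds = generate_synthetic_dataset(SynthSpec(n_classes=4, per_class=10,
                                              image_size=32, seed=11))
    return split_dataset(ds, SplitSpec(seed=11))
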