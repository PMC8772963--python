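import numpy as np
import pytest

from pemnet.phantom import DEFAULT_MLO_RANGES, PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def small_phantom_base():
    return PhantomSpec(width=128, height=128, margin=4)


@pytest.fixture(scope="session")
def mlo_batch(small_phantom_base):
    """20 mixed-laterality MLO phantoms with artefacts, 128x128."""
    samples, _ = generate_dataset(20, DEFAULT_MLO_RANGES, seed=910,
                                  base_spec=small_phantom_base)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
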