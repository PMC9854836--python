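import numpy as np
import pytest

from gutseg.phantoms import PhantomConfig, generate_slices


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small in-memory phantom cohort shared across tests."""
    cfg = PhantomConfig(n_cases=2, min_days=1, max_days=1, slices_per_scan=4,
                        image_size=64, seed=7)
    return generate_slices(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_binary_mask(rng, h, w, p=0.3):
    return (rng.random((h, w)) < p).astype(np.uint8)
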