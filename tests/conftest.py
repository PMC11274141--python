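import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240702)


@pytest.fixture
def random_gray(rng):
    """Factory for random uint8 images."""
    def make(h=16, w=16):
        return rng.integers(0, 256, size=(h, w), dtype=np.uint8)
    return make


@pytest.fixture
def random_mask(rng):
    """Factory for random {0, 255} binary masks.

    ``margin`` rows/cols of background inside the frame keep the white set
    away from the border, so morphological identities that presume infinite
    support (extensivity, idempotence) hold exactly despite the operators'
    everything-outside-is-background convention.
    """
    def make(h=12, w=12, p=0.5, margin=0):
        mask = np.where(rng.random((h, w)) < p, 255, 0).astype(np.uint8)
        if margin:
            mask[:margin] = mask[-margin:] = 0
            mask[:, :margin] = mask[:, -margin:] = 0
        return mask
    return make


@pytest.fixture
def quiet_phantom():
    """Noiseless, calculus-free phantom with its truth (shared across tests)."""
    from bitewing import PhantomSpec, generate_bitewing
    spec = PhantomSpec(noise_sigma=0.0, calculus_probability=0.0, seed=11)
    return generate_bitewing(spec)
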