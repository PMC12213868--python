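import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantoms():
    """Four 64-px phantoms with one or two lesions each (deterministic)."""
    from mixerseg import PhantomConfig, generate_phantoms

    cfg = PhantomConfig(n_images=4, seed=11, size=64, lesions_range=(1, 2))
    phantoms = generate_phantoms(cfg)
    images = np.stack([p.image for p in phantoms])[..., None].astype(np.float32)
    masks = np.stack([p.mask for p in phantoms])[..., None].astype(np.float32)
    return images, masks
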