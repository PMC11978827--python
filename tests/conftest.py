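import numpy as np
import pytest

from neurofusion.model import CrossModalModel, ModelConfig
from neurofusion.synthetic_data import SyntheticConfig, generate_pairs

SMALL_IMG = 28  # smallest tiny_conv-compatible image size; keeps tests fast


@pytest.fixture(scope="session")
def small_pairs():
    cfg = SyntheticConfig(n_samples=16, n_vox=60, n_roi=6, img_size=SMALL_IMG,
                          alignment_strength=0.9, noise_sd=0.1, seed=11)
    return generate_pairs(cfg)


@pytest.fixture(scope="session")
def small_model(small_pairs):
    mc = ModelConfig(d=16, img_size=SMALL_IMG)
    mc.timeformer.n_heads = 2
    return CrossModalModel(mc, small_pairs.grid, n_roi=6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
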