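import numpy as np
import pytest

from tomaformer.encoder import EncoderConfig
from tomaformer.model import ModelConfig
from tomaformer.scenes import SceneConfig
from tomaformer.transformer import TransformerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_config():
    """Smallest model that keeps the full 11-SPB/5-RB structure."""
    return ModelConfig(
        encoder=EncoderConfig(width_multiplier=0.25),
        transformer=TransformerConfig(width=32, heads=2, ff_width=64),
    )


@pytest.fixture
def simple_scene_config():
    """Occlusion-free scene with a few large fruit: the overfit regime."""
    return SceneConfig(n_tomatoes_range=(2, 3), radius_range=(10, 14),
                       occlusion_density=0.0, lighting_gain_range=(1.0, 1.0),
                       seed=0)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
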