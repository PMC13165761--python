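import numpy as np
import pytest

from pestfusion import MultimodalDataset, SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene_config():
    """Small, fast study configuration shared by the model-level tests."""
    return SceneConfig(n_samples=48, patch_size=32, window_len=24, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_scene_config) -> MultimodalDataset:
    return MultimodalDataset.from_samples(
        generate_dataset(small_scene_config))
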