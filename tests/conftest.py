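import numpy as np
import pytest

from segnew import FeatureExtractorSpec, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Cheap extractor spec for unit tests: one scale, no gradient histogram."""
    return FeatureExtractorSpec(scales=(1,), window=1, params={"stride": 4, "grad_bins": 0})


@pytest.fixture
def default_spec():
    return FeatureExtractorSpec()


@pytest.fixture
def rgb_scene_spec():
    return SceneSpec(domain="rgb", seed=7)


@pytest.fixture
def intensity_scene_spec():
    return SceneSpec(domain="intensity", seed=7)
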