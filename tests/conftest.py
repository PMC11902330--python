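import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight small, easy synthetic scenes (module-level cache)."""
    from gpcyolo.data import SceneSpec, generate_scenes

    spec = SceneSpec(n_images=8, image_size=320, objects_per_image=(2, 4),
                     overlap_prob=0.1, occlusion_prob=0.1,
                     illumination_jitter=0.15, rng_seed=0)
    return generate_scenes(spec)


@pytest.fixture(scope="session")
def small_gpc_model():
    """A gpc-variant model at 128 px input, shared across read-only tests."""
    from gpcyolo.network import build_model, variant_config

    return build_model(variant_config("gpc", input_size=128), seed=0)
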