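import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from agbmap.config import PipelineConfig
from agbmap.synthetic_data import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    return SceneConfig(rows=120, cols=120, seed=42)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full in-memory pipeline run shared across tests (seed 1)."""
    from agbmap.pipeline import run_end_to_end

    return run_end_to_end(PipelineConfig().with_seed(1))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
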