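import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_two_arm():
    """A small cross-sectional two-arm dataset with a known 0.5 s.d. effect."""
    from trialforest import GeneratorTruth, gen_cross_sectional

    ds, truth = gen_cross_sectional(
        400, truth=GeneratorTruth(true_ate_per_arm=(0.5,)), seed=7
    )
    return ds, truth


@pytest.fixture
def fast_config():
    """Small sampler settings for unit tests (not the analysis defaults)."""
    from trialforest import BCFConfig

    return BCFConfig(
        n_trees_prognostic=40,
        n_trees_moderator=15,
        draws=250,
        burnin=150,
        seed=5,
    )
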