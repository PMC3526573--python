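"""Shared fixtures: small synthetic images and a pre-trained classifier.

Unit and pipeline tests run on 256x256 synthetic fields with 25-60 px
colonies so the whole suite stays fast; the acceptance tests use the
full-size 500x500 defaults.
"""

import numpy as np
import pytest

from colonyscan.classifier import FeatureConfig, train
from colonyscan.synthetic import GeneratorConfig, make_training_set

SMALL_KW = dict(shape=(256, 256), radius=(25.0, 60.0), n_colonies=(1, 3))


def small_config(seed, **overrides):
    kw = {**SMALL_KW, **overrides}
    return GeneratorConfig(**kw, seed=seed)


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def small_training_set():
    configs = [small_config(200 + i) for i in range(3)]
    return make_training_set(configs, pixels_per_image=6000, seed=42)


@pytest.fixture(scope="session")
def small_model(small_training_set):
    return train(small_training_set, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
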