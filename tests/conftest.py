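"""Shared fixtures: small trained lobes and scene sets, built once per session."""

import numpy as np
import pytest

import lobulanet as ln
from lobulanet.experiments import make_training_scenes


@pytest.fixture(scope="session")
def scenes():
    return make_training_scenes(10, seed=0)


@pytest.fixture(scope="session")
def trained_lobe_small(scenes):
    """A 16-unit visual lobe trained briefly on synthetic scenes."""
    cfg = ln.LearningConfig(n_patches=1500, seed=0)
    lobe, _ = ln.train_visual_lobe(scenes, cfg, n_lobula=16)
    return lobe


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
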