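"""Shared fixtures: one synthetic benchmark slide and one trained classifier,
built once per session because segmentation and feature extraction dominate
test runtime."""

import warnings

import numpy as np
import pytest

from tilquant import SlideSpec, generate_slide
from tilquant.classification import train_classifier
from tilquant.pipeline import build_training_set

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def benchmark_slide():
    """1000x1000 slide with 200 non-touching nuclei and known ground truth."""
    spec = SlideSpec(
        width_px=1000,
        height_px=1000,
        n_nuclei=200,
        class_fractions=(0.5, 0.2, 0.3),
        seed=7,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def training_set_aegj():
    return build_training_set("AEGJ", n_per_class=80, seed=1)


@pytest.fixture(scope="session")
def trained_model(training_set_aegj):
    return train_classifier(training_set_aegj, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
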