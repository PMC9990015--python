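"""Shared fixtures: phantoms and classifiers at two cost tiers.

``study_classifier`` is the expensive session fixture: the reference network
trained under the full study settings (200 patches/class at 32x32x3, 25
epochs); quick contract tests use ``quick_classifier`` (2 epochs, small
sample) instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from pulmotex.models import TrainSpec, build_denres_mini, train
from pulmotex.phantom import (
    default_phantom_spec,
    generate_phantom,
    preprocess_phantom,
    sample_labeled_patches,
)

PATCH32 = (32, 32, 3)


@pytest.fixture(scope="session")
def study_phantom():
    """Default six-class phantom, preprocessed the way the pipeline sees it."""
    return preprocess_phantom(generate_phantom(default_phantom_spec(seed=0)))


@pytest.fixture(scope="session")
def study_patches(study_phantom):
    return sample_labeled_patches(study_phantom, PATCH32, 200, seed=1)


@pytest.fixture(scope="session")
def study_classifier(study_patches):
    """25-epoch training run under the study protocol (shared; ~1 min)."""
    clf = build_denres_mini(PATCH32, seed=2)
    clf, history = train(clf, study_patches, TrainSpec(epochs=25, seed=3))
    return clf, history


@pytest.fixture(scope="session")
def quick_phantom():
    return generate_phantom(default_phantom_spec(seed=5, shape=(128, 128, 6)))


@pytest.fixture(scope="session")
def quick_classifier(quick_phantom):
    """Cheap partially-trained classifier for contract and plumbing tests."""
    patches = sample_labeled_patches(quick_phantom, PATCH32, 25, seed=6)
    clf = build_denres_mini(PATCH32, seed=7)
    clf, _ = train(clf, patches, TrainSpec(epochs=2, seed=8))
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
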