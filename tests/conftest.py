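"""Shared fixtures: fast phantom geometries and a session-scoped trained
classifier (training is the most expensive fixture, so it is built once and
reused by the classifier tests and the end-to-end suite)."""

from __future__ import annotations

import numpy as np
import pytest

from slitscreen import classifier as clf
from slitscreen import phantom


@pytest.fixture(scope="session")
def fast_params() -> phantom.EyePhantomParams:
    """Small, short phantom for unit tests (40 frames, 120 x 90)."""
    return phantom.EyePhantomParams(
        image_width=120,
        image_height=90,
        pupil_center=(60, 45),
        pupil_radius=14,
        iris_radius=30,
        sclera_margin=12,
        duration_s=2.0,
        fps=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_video():
    """One default-parameter protocol-A video with its ground truth."""
    params = phantom.EyePhantomParams(protocol="A", seed=3)
    frames, truth = phantom.generate_video(params)
    return params, list(frames), truth


@pytest.fixture(scope="session")
def trained_classifier():
    """Reference classifier fitted on 200 synthetic crops (100 per class)."""
    crops, labels = phantom.in_pupil_crop_dataset(100, seed=123)
    config = clf.TrainConfig(epochs=20, batch_size=16, seed=0)
    model = clf.train_reference_classifier(crops, labels, config)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
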