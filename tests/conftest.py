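"""Shared fixtures: a small easy phantom cohort and a briefly trained
CNN, generated once per session (all data is synthesized at test time)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arlnet import models, phantom


@pytest.fixture(scope="session")
def small_config() -> phantom.PhantomConfig:
    return phantom.PhantomConfig(
        n_patients=12, images_per_patient=3, image_size=32,
        nodule_radius_range=(4.0, 7.0), nodule_contrast=0.5,
        background_noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return phantom.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_arrays(small_cohort):
    return phantom.cohort_arrays(small_cohort)


@pytest.fixture(scope="session")
def tiny_trained_model(small_arrays):
    """A simple CNN trained briefly on the small cohort (enough to be a
    meaningful feature extractor / Grad-CAM subject, not to converge)."""
    X, y, _ = small_arrays
    model = models.build_simple_cnn(models.ModelSpec("simple_cnn", input_size=32, seed=1))
    models.train_model(model, (X, y), None,
                       models.TrainConfig(epochs=6, batch_size=12,
                                          learning_rate=2e-3, seed=1))
    return model


def make_manifest(n_patients: int, images_per_patient: int = 38) -> pd.DataFrame:
    """Balanced image-level manifest without pixel data (split tests)."""
    rows = []
    for p in range(n_patients):
        label = p % 2
        for i in range(images_per_patient):
            rows.append({"patient_id": f"P{p:04d}",
                         "image_id": f"P{p:04d}_I{i:03d}", "label": label})
    return pd.DataFrame(rows)


@pytest.fixture
def manifest_160() -> pd.DataFrame:
    return make_manifest(160)
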