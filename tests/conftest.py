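"""Shared fixtures: micro-scale model configs and small synthetic datasets.

Everything is generated programmatically and seeded; nothing is read from
disk.  The micro configuration is deliberately tiny so whole-model tests
(training schedules, perturbation engines, relevance propagation) run in
seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from filterscope import (
    BandComponent,
    ClassRecipe,
    ModelConfig,
    TrainConfig,
    build_model,
    generate_dataset,
    zscore_per_subject,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def micro_config() -> ModelConfig:
    """Smallest architecture that still exercises the full layer cascade."""
    return ModelConfig(
        input_len=60, fs=20.0, n_filters1=2, filter_len1=8,
        pool1_size=5, pool1_stride=5, n_filters2=4, filter2_shape=(3, 2),
        pool2_size=(2, 1), pool2_stride=(1, 1), dense_sizes=(8,), n_classes=2,
    )


@pytest.fixture
def micro_model(micro_config):
    return build_model(micro_config, seed=7)


@pytest.fixture
def micro_dataset(micro_config):
    """Two-class dataset shaped for the micro model: 3 Hz vs 8 Hz tones."""
    recipes = [
        ClassRecipe(name="lo", class_prior=0.5,
                    band_components=(BandComponent(3.0, 0.5, 2.0),)),
        ClassRecipe(name="hi", class_prior=0.5,
                    band_components=(BandComponent(8.0, 0.5, 2.0),)),
    ]
    ds = generate_dataset(recipes, n_subjects=4, windows_per_subject=10,
                          fs=20.0, window_seconds=3.0, seed=99)
    return zscore_per_subject(ds)


@pytest.fixture
def small_train_config() -> TrainConfig:
    return TrainConfig(batch_size=20, max_epochs=8, lr_init=0.05,
                       early_stop_patience=8, seed=3)
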