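"""Shared fixtures: synthetic datasets and desk-scale trained models.

The expensive end-to-end fixture (7-class data, trained segmenter and
classifier) is session-scoped so the full-pipeline checks share one
training run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from skinet.nets import (BayesianNetSpec, build_bayesian_classifier,
                         build_bayesian_multiresunet)
from skinet.synthetic import SyntheticConfig, generate_dataset
from skinet.training import TrainConfig, train_classifier, train_segmenter, \
    train_validation_split

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_3class():
    """3-class separable data (100/class, 32x32) and a trained classifier."""
    cfg = SyntheticConfig(image_height=32, image_width=32, n_classes=3,
                          artifact_rate=0.2, seed=42)
    samples, _ = generate_dataset(cfg, 100)
    train, val = train_validation_split(samples, 0.2, seed=1)
    spec = BayesianNetSpec(kind="classifier", input_size=(32, 32), n_classes=3,
                           base_filters=8, dropout_rate=0.5, seed=5)
    model = build_bayesian_classifier(spec, n_stages=4)
    model, history = train_classifier(
        model, train, TrainConfig(epochs=10, batch_size=32, seed=3))
    return {"config": cfg, "train": train, "val": val, "model": model,
            "history": history}


@dataclasses.dataclass
class EndToEnd:
    config: SyntheticConfig
    train: list
    val: list
    classifier: object
    cls_history: list
    segmenter: object
    seg_history: list


@pytest.fixture(scope="session")
def end_to_end():
    """The full desk-scale study: 7 classes x 200 samples at 32x32,
    trained Bayesian classifier and MultiResUNet segmenter."""
    cfg = SyntheticConfig(image_height=32, image_width=32, n_classes=7,
                          seed=7)
    samples, _ = generate_dataset(cfg, 200)
    train, val = train_validation_split(samples, 0.2, seed=1)

    cls_spec = BayesianNetSpec(kind="classifier", input_size=(32, 32),
                               n_classes=7, base_filters=8,
                               dropout_rate=0.5, seed=5)
    classifier = build_bayesian_classifier(cls_spec, n_stages=4)
    classifier, cls_hist = train_classifier(
        classifier, train, TrainConfig(epochs=15, batch_size=32, seed=3))

    seg_spec = BayesianNetSpec(kind="segmenter", input_size=(32, 32),
                               base_filters=8, dropout_rate=0.5, seed=5)
    segmenter = build_bayesian_multiresunet(seg_spec)
    segmenter, seg_hist = train_segmenter(
        segmenter, train[:100], TrainConfig(epochs=12, batch_size=8, seed=3))

    return EndToEnd(cfg, train, val, classifier, cls_hist, segmenter, seg_hist)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
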