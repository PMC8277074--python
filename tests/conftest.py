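"""Shared fixtures.

The trained models are expensive (a few hundred epochs each), so they
are built once per session on the standard separable three-component
benchmark and shared by the training, generation and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from moesimvae import (STUDY_TRAIN_KWARGS, SyntheticSpec, simulate,
                       study_model_config, study_similarity_spec, train)

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study_data():
    """Separable 3-component Gaussian-mixture benchmark dataset."""
    data, labels, params = simulate(SyntheticSpec(k_true=3, seed=STUDY_SEED))
    return data, labels, params


def _train(data, **overrides):
    cfg = study_model_config(15, data.shape[1], seed=STUDY_SEED, **overrides)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train(data, cfg, study_similarity_spec(STUDY_SEED),
                     seed=STUDY_SEED, **STUDY_TRAIN_KWARGS)


@pytest.fixture(scope="session")
def trained(study_data):
    """Model trained with the full objective on the benchmark."""
    data, _, _ = study_data
    return _train(data)


@pytest.fixture(scope="session")
def trained_no_similarity(study_data):
    """Same run with the similarity loss weighted to zero (ablation)."""
    data, _, _ = study_data
    return _train(data, similarity_weight=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
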