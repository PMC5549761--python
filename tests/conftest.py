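"""Shared fixtures: banks, corpora and one desk-scale trained model.

The expensive artifacts (the 2400-dim energy bank, the synthetic corpora
and the end-to-end trained mixture) are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mixsc.config import LearningConfig, RunConfig
from mixsc.gabor import FrontendConfig, build_energy_bank
from mixsc.learning import train_mixture
from mixsc.protocols import full_variation_protocol, sweep_protocol
from mixsc.synth import make_face_corpus, make_object_corpus

# desk-scale study conditions: 500 images per class, reduction to 30
# dimensions, 60 units per submodel, 2000 full-variation stimuli with 1000
# surrogates per feature
N_CORPUS = 500
DESK_LEARNING = LearningConfig(n_reduced=30, n_units=60)
N_STIMULI = 2000
N_SURROGATES = 1000


@pytest.fixture(scope="session")
def default_bank():
    return build_energy_bank()


@pytest.fixture(scope="session")
def small_bank():
    return build_energy_bank(
        FrontendConfig(grid=4, n_orientations=4, frequencies=(0.25, 0.13))
    )


@pytest.fixture(scope="session")
def corpora():
    faces = make_face_corpus(N_CORPUS, seed=10)
    objects = make_object_corpus(N_CORPUS, seed=11)
    return faces, objects


@pytest.fixture(scope="session")
def desk_config():
    return RunConfig(learning=DESK_LEARNING)


@pytest.fixture(scope="session")
def desk_model(corpora, desk_config):
    faces, objects = corpora
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return train_mixture(
            faces.split()[0], objects.split()[0], desk_config, seed=12
        )


@pytest.fixture(scope="session")
def full_variation(desk_model, default_bank):
    return full_variation_protocol(
        desk_model,
        n_stimuli=N_STIMULI,
        n_surrogates=N_SURROGATES,
        seed=13,
        bank=default_bank,
    )


@pytest.fixture(scope="session")
def sweep_curves(desk_model, default_bank):
    single, single_post = sweep_protocol(desk_model, "single", bank=default_bank)
    partial, partial_post = sweep_protocol(desk_model, "partial", bank=default_bank)
    return {
        "single": single,
        "single_post": single_post,
        "partial": partial,
        "partial_post": partial_post,
    }
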