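"""Shared fixtures: one default synthetic world, built once per session."""

import numpy as np
import pytest

from catselect import (
    LocalizerDesign,
    PlantedModelConfig,
    StimulusConfig,
    build_planted_model,
    forward_activations,
    generate_stimulus_set,
    localize_selective_units,
)

SEED = 11


@pytest.fixture(scope="session")
def stimulus_set():
    return generate_stimulus_set(StimulusConfig(), SEED)


@pytest.fixture(scope="session")
def model(stimulus_set):
    return build_planted_model(stimulus_set, PlantedModelConfig(), SEED + 1)


@pytest.fixture(scope="session")
def store(model, stimulus_set):
    return forward_activations(model, stimulus_set)


@pytest.fixture(scope="session")
def design():
    return LocalizerDesign()


@pytest.fixture(scope="session")
def smap(store, design):
    return localize_selective_units(store, design)


@pytest.fixture(scope="session")
def smap_post(store, design):
    return localize_selective_units(store, design, stages=("post",))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
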