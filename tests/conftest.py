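"""Shared fixtures: small pseudo-real dishes and a session-scoped cutout bank."""

from __future__ import annotations

import numpy as np
import pytest

from petrisynth.config import GenConfig
from petrisynth.fixtures import FixtureConfig, make_annotated_dish, make_empty_dish
from petrisynth.pipeline import build_bank


@pytest.fixture(scope="session")
def gen_config() -> GenConfig:
    return GenConfig()


@pytest.fixture(scope="session")
def small_dish():
    """One annotated fixture dish with ground-truth masks."""
    rng = np.random.default_rng(42)
    return make_annotated_dish(FixtureConfig(n_colonies=4), rng, species="E.coli")


@pytest.fixture(scope="session")
def empty_dish_small():
    rng = np.random.default_rng(7)
    return make_empty_dish(FixtureConfig(), rng)


@pytest.fixture(scope="session")
def empty_dish_large():
    """Background dish large enough for 256-px crops at any rotation."""
    rng = np.random.default_rng(8)
    return make_empty_dish(FixtureConfig(dish_diameter=768), rng, source_id="bg_large")


@pytest.fixture(scope="session")
def cutout_bank(gen_config):
    """Cutouts extracted from one fixture dish per species (built once)."""
    annotated = []
    for k, sp in enumerate(gen_config.species_set):
        rng = np.random.default_rng(100 + k)
        dish, _ = make_annotated_dish(
            FixtureConfig(n_colonies=3), rng, species=sp, source_id=f"bankdish_{k}"
        )
        annotated.append(dish)
    return build_bank(annotated, gen_config)
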