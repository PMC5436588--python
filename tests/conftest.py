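"""Shared fixtures: small synthetic scenarios kept cheap for unit tests.

The full-size default scenario (~1,259 cells) is reserved for the
acceptance suite; unit tests run on a 30–35 km island with a scaled-down
road program so each fixture builds in a couple of seconds.
"""

from __future__ import annotations

import warnings

import pytest

from forestscape.synthetic import SyntheticScenario, generate_dataset

#: road program for the small island (same shape as the default: main roads
#: keep growing, the secondary network freezes after the second period)
SMALL_GROWTH = ((12, 150), (10, 160), (8, 0), (10, 0))


def small_scenario(**overrides) -> SyntheticScenario:
    kwargs = dict(seed=42, island_radius_km=32.0, road_growth=SMALL_GROWTH, n_towns=6)
    kwargs.update(overrides)
    return SyntheticScenario(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """A ~50-cell island with the default generative rule, built once."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(small_scenario())


@pytest.fixture(scope="session")
def small_dataset_with_masks():
    """Same island, noise-free, with 100-m forest-mask rasters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(small_scenario(noise_sd=0.0), with_forest_masks=True)
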