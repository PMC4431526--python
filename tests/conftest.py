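import dataclasses

import pytest

import wormscreen as ws


@pytest.fixture(scope="session")
def small_config() -> ws.SyntheticScreenConfig:
    """Two-plate screen, small enough for fast unit tests."""
    return ws.SyntheticScreenConfig(
        n_plates=2,
        genes_per_plate=24,
        enhancer_fraction=0.15,
        suppressor_fraction=0.05,
        lethal_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    """A generated screen (wells, truth) shared across read-only tests."""
    return ws.generate_screen(small_config, seed=11)


@pytest.fixture()
def strong_effect_config(small_config) -> ws.SyntheticScreenConfig:
    """Low-noise screen with unambiguous planted effects."""
    return dataclasses.replace(
        small_config,
        enhancer_effect=(0.2, 0.2),
        lethal_fraction=0.0,
        dispersion=1e4,
        plate_effect_sd=0.02,
    )
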