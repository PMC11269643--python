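"""Shared fixtures: small synthetic worlds and derived datasets."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from climenv import (
    SyntheticWorldConfig,
    TrueResponse,
    annual_bioclim_series,
    climatology,
    generate_climate,
)


@pytest.fixture(scope="session")
def small_world() -> SyntheticWorldConfig:
    """A 4x4-cell, 5-year world: fast enough for per-test regeneration."""
    return SyntheticWorldConfig(
        lat_min=50.0, lat_max=51.0, lon_min=5.0, lon_max=6.0,
        resolution=0.25, year_start=2000, year_end=2004, seed=7,
    )


@pytest.fixture(scope="session")
def small_climate(small_world):
    return generate_climate(small_world)


@pytest.fixture(scope="session")
def small_bioclim(small_climate):
    return annual_bioclim_series(small_climate)


@pytest.fixture(scope="session")
def wide_world() -> SyntheticWorldConfig:
    """A latitudinally wide world whose BIO1 spans ~9 degC: envelopes fit

    inside the sampled range, which the envelope-recovery tests need."""
    return SyntheticWorldConfig(
        lat_min=44.0, lat_max=60.0, lon_min=5.0, lon_max=15.0,
        resolution=0.5, year_start=1981, year_end=2010,
        warming_trend=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def wide_climatology(wide_world):
    return climatology(annual_bioclim_series(generate_climate(wide_world)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240724)
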