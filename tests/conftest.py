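"""Shared fixtures: acquisition configs and the reduced-scale imaging system."""

from __future__ import annotations

import numpy as np
import pytest

from mwisar import (
    AngularSweep,
    AntennaConfig,
    ForwardConfig,
    FrequencySweep,
    ImagingGrid,
    build_sensitivity,
    pinv_svd,
)

CONTAINER_RADIUS = 0.085
MEDIUM_EPS_R = 80.0


@pytest.fixture(scope="session")
def reduced_cfg() -> ForwardConfig:
    """Desk-scale acquisition: 64 freqs 0.1-4.8 GHz, 90 angles, R0 = 8.5 cm."""
    return ForwardConfig(
        antenna=AntennaConfig(CONTAINER_RADIUS),
        sweep=FrequencySweep(0.1e9, 4.8e9, 64),
        rotation=AngularSweep(90),
    )


@pytest.fixture(scope="session")
def reduced_grid() -> ImagingGrid:
    return ImagingGrid(32, 0.08)


@pytest.fixture(scope="session")
def reduced_system(reduced_cfg, reduced_grid):
    """Sensitivity matrix and its pseudo-inverse at the reduced scale.

    J is 5760 x 1024; built once per session and shared by the round-trip
    and noise-robustness tests.
    """
    J = build_sensitivity(
        reduced_grid, MEDIUM_EPS_R, reduced_cfg, container_radius=CONTAINER_RADIUS
    )
    return J, pinv_svd(J)


@pytest.fixture(scope="session")
def tiny_cfg() -> ForwardConfig:
    """Very small acquisition for fast unit tests (16 freqs, 20 angles)."""
    return ForwardConfig(
        antenna=AntennaConfig(CONTAINER_RADIUS),
        sweep=FrequencySweep(0.1e9, 4.8e9, 16),
        rotation=AngularSweep(20),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
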