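"""Shared fixtures: reference geometry and (cached) surrogate simulations."""
from __future__ import annotations

import numpy as np
import pytest

from memthin import ZoneGeometry


@pytest.fixture(scope="session")
def ref_geom() -> ZoneGeometry:
    """Reference zone layout: 55 nm box, 10 nm thin and buffer zones."""
    return ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)


@pytest.fixture(scope="session")
def small_geom() -> ZoneGeometry:
    """Desk-scale layout with the same thin:buffer:box proportions."""
    return ZoneGeometry(X_box=16.0, A_thin=4.0, A_buffer=3.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
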