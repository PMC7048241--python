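"""Shared fixtures.

Session-scoped Monte Carlo runs are cached here so the statistical tests
reuse transport results instead of re-simulating per test.  Photon numbers
are scaled to keep the whole suite fast while leaving enough statistics for
the trend and band assertions; see docs/methods.md for the choices.
"""

from __future__ import annotations

import numpy as np
import pytest

import ppgmc
from ppgmc.transport import SensorGeometry, TransportConfig, run_simulation


@pytest.fixture(scope="session")
def buccal_model():
    return ppgmc.builtin_buccal_model()


@pytest.fixture(scope="session")
def blood():
    return ppgmc.BloodOpticalProperties.default()


@pytest.fixture(scope="session")
def nominal():
    return ppgmc.NOMINAL_PERFUSION


@pytest.fixture(scope="session")
def contact_raw_660(buccal_model, blood, nominal):
    """Contact-geometry run at 660 nm, nominal perfusion."""
    cfg = TransportConfig(n_detect_target=2000, seed=11)
    return run_simulation(
        buccal_model, SensorGeometry(), nominal, blood, 660.0, cfg
    )


@pytest.fixture(scope="session")
def contact_raw_880(buccal_model, blood, nominal):
    cfg = TransportConfig(n_detect_target=2000, seed=11)
    return run_simulation(
        buccal_model, SensorGeometry(), nominal, blood, 880.0, cfg
    )


def mc_rng(seed: int = 0) -> np.random.Generator:
    """Seeded generator for sampling-statistics tests."""
    return np.random.default_rng(seed)
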