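"""Shared fixtures: one Monte Carlo run and one lookup table per session.

The photon transport kernel is by far the most expensive component, so the
suite shares a single 400k-photon lookup-table build and a single detected
record set at 30 mm across all tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

from tdmom.transport import (
    TableConfig,
    TissueModel,
    build_lookup_table,
    run_mc,
)


@pytest.fixture(scope="session")
def model():
    return TissueModel()


@pytest.fixture(scope="session")
def table(model):
    """Default-grid sensitivity lookup table (~20 s single CPU)."""
    return build_lookup_table(model, TableConfig(n_photons=400_000, seed=12345))


@pytest.fixture(scope="session")
def records30(model):
    """Detected photon records at 30 mm separation (~20 s single CPU)."""
    return run_mc(model, separation=30.0, n_photons=400_000, seed=99)


@pytest.fixture(scope="session")
def records8(model):
    """Detected photon records at 8 mm separation (cheap: dense ring)."""
    return run_mc(model, separation=8.0, n_photons=60_000, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(20241001)
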