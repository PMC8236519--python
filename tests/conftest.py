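"""Shared fixtures.

The dendrite trunk and the epsilon classification sweep are expensive
(minutes of simulation), so they are computed once per session and shared by
the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinepattern import experiments as ex
from spinepattern.params import Grid, ModelParams, SimSchedule, preset


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid(nx=6, ny=7, dx=0.3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fig4_params() -> ModelParams:
    return preset("fig4", epsilon=0.01)


@pytest.fixture(scope="session")
def trunk_state():
    """Stage-1 dendrite trunk (grown once per session)."""
    return ex.grow_trunk()


@pytest.fixture(scope="session")
def epsilon_sweep():
    """Single-spine classification along the acceptance epsilon scans."""
    fine = [round(0.01 * k, 2) for k in range(1, 10)]
    coarse = [round(0.05 * k, 2) for k in range(1, 19)]
    values = sorted(set(fine + coarse))
    return ex.sweep_epsilon_shapes(values)
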