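"""Shared fixtures.

The expensive simulations (settled single-cell runs, half-size tissue
runs) are session-scoped so the acceptance checks and unit tests share
them; everything is generated programmatically, no stored data.
"""

import numpy as np
import pytest

from biopace import run_cell, run_tissue, build_geometry
from biopace.single_cell import PACEMAKER_G_K1, STABLE_SETTLE_MS
from biopace.tnnp06 import CellParameters


@pytest.fixture(scope="session")
def settled_base_trace():
    """Pacemaker cell (g_K1 = 0.05, defaults otherwise) at the
    concentration steady state; 20 s recorded at 0.1 ms."""
    p = CellParameters(g_K1=PACEMAKER_G_K1)
    return run_cell(p, duration=20_000.0, record_stride=0.1,
                    settle_ms=STABLE_SETTLE_MS)


@pytest.fixture(scope="session")
def settled_gna0_trace():
    p = CellParameters(g_K1=PACEMAKER_G_K1, g_Na=0.0)
    return run_cell(p, duration=20_000.0, record_stride=0.1,
                    settle_ms=STABLE_SETTLE_MS)


@pytest.fixture(scope="session")
def settled_gna30_trace():
    p = CellParameters(g_K1=PACEMAKER_G_K1, g_Na=30.0)
    return run_cell(p, duration=20_000.0, record_stride=0.1,
                    settle_ms=STABLE_SETTLE_MS)


@pytest.fixture(scope="session")
def case1_small_run():
    """Half-size Case 1: all endocardial columns paced, normal
    currents and coupling, 3 s."""
    geom = build_geometry(12, 1.0, nx=50, ny=25)
    return run_tissue(geom, duration=3000.0)


@pytest.fixture(scope="session")
def weak_coupling_small_run():
    """Half-size weak-coupling pacemaker (D fraction 0.09), 3 s."""
    geom = build_geometry(11, 0.09, nx=50, ny=25)
    return run_tissue(geom, duration=3000.0)
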