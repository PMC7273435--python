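"""Geometry, diffusion operator and monodomain solver tests."""

import numpy as np
import pytest

from biopace import (
    build_geometry,
    classify_drive,
    laplacian_term,
    run_cell,
    run_tissue,
)
from biopace.scenarios import make_test_fixture
from biopace.tissue import TissueRun, D_NORMAL_CM2_S, _CM2S_TO_MM2MS
from biopace.tnnp06 import CellParameters


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_default_geometry_column_split():
    g = build_geometry(23, 0.09)
    assert (g.nx, g.ny) == (100, 50)
    counts = [(g.cell_type_map == c).sum() for c in (0, 1, 2)]
    assert counts == [25 * 50, 35 * 50, 40 * 50]
    assert g.pacemaker_mask.sum() == 23 * 50
    # weak-coupling pacemaker: D = 0.09 x 0.154 = 0.01386 cm^2/s
    assert g.D[g.pacemaker_mask] == pytest.approx(0.01386)
    assert g.D[~g.pacemaker_mask] == pytest.approx(0.154)


def test_no_pacemaker_geometry_is_uniform():
    g = build_geometry(0)
    assert not g.pacemaker_mask.any()
    assert np.unique(g.D).size == 1


def test_case1_geometry_uniform_d():
    g = build_geometry(25, 1.0)
    assert g.pacemaker_mask.sum() == 25 * 50
    assert np.unique(g.D).size == 1


def test_pacemaker_confined_to_endocardium():
    with pytest.raises(ValueError, match="endocardial"):
        build_geometry(26)


# ---------------------------------------------------------------------------
# diffusion operator
# ---------------------------------------------------------------------------

def test_uniform_field_has_zero_laplacian():
    V = np.full((8, 9), -52.3)
    D = np.full((8, 9), D_NORMAL_CM2_S)
    assert np.allclose(laplacian_term(V, D), 0.0, atol=1e-14)


def test_laplacian_conserves_total_voltage():
    """No-flux boundaries: the operator redistributes but never creates."""
    rng = np.random.default_rng(7)
    V = rng.normal(-60, 30, (10, 12))
    D = rng.uniform(0.01, 0.2, (10, 12))
    term = laplacian_term(V, D)
    assert term.sum() == pytest.approx(0.0, abs=1e-10 * np.abs(term).max())


def test_laplacian_matches_bruteforce_loop():
    """Flux-form stencil vs an explicit per-cell loop, heterogeneous D."""
    V = make_test_fixture("random_field", seed=1, shape=(6, 5))
    rng = np.random.default_rng(2)
    D = rng.uniform(0.0, 0.2, (6, 5))
    dx = 0.15
    expect = np.zeros_like(V)
    ny, nx = V.shape
    for i in range(ny):
        for j in range(nx):
            acc = 0.0
            for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                ii, jj = i + di, j + dj
                if 0 <= ii < ny and 0 <= jj < nx:
                    dface = 0.5 * (D[i, j] + D[ii, jj]) * _CM2S_TO_MM2MS
                    acc += dface * (V[ii, jj] - V[i, j])
            expect[i, j] = acc / dx**2
    assert np.allclose(laplacian_term(V, D, dx), expect, rtol=1e-13, atol=1e-13)


def test_laplacian_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        laplacian_term(np.zeros((3, 3)), np.zeros((3, 4)))


def test_diffusion_only_dynamics_conserve_sum():
    """Explicit Euler with the operator alone keeps sum(V) constant and
    relaxes towards a uniform field."""
    rng = np.random.default_rng(3)
    V = rng.normal(-60, 20, (6, 6))
    D = np.full((6, 6), D_NORMAL_CM2_S)
    total0 = V.sum()
    for _ in range(2000):
        V = V + 0.02 * laplacian_term(V, D)
    assert V.sum() == pytest.approx(total0, rel=1e-12)
    assert V.std() < 1.0


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def test_cfl_violation_rejected():
    g = build_geometry(0, nx=8, ny=4, column_split=(2, 3, 3))
    with pytest.raises(ValueError, match="CFL"):
        run_tissue(g, duration=1.0, dt=0.5)


def test_decoupled_tissue_matches_single_cell_exactly():
    """With D = 0 each grid cell reproduces its single-cell trajectory
    bit-for-bit (reaction-diffusion decoupling oracle)."""
    g = build_geometry(2, 0.0, nx=4, ny=4, column_split=(2, 1, 1),
                       D_normal=0.0)
    run = run_tissue(g, duration=400.0, snapshot_interval=1.0)
    # pacemaker endocardial cell
    ref = run_cell(CellParameters(g_K1=0.05), duration=400.0,
                   record_stride=1.0)
    _, v_tissue = run.cell_trace(0, 0)
    assert np.array_equal(np.float32(ref.V), np.float32(v_tissue))
    # epicardial cell (rightmost column), default parameters
    ref_epi = run_cell(CellParameters.for_cell_type("epicardial"),
                       duration=400.0, record_stride=1.0)
    _, v_epi = run.cell_trace(3, 3)
    assert np.array_equal(np.float32(ref_epi.V), np.float32(v_epi))


def test_snapshot_bookkeeping():
    g = build_geometry(1, 1.0, nx=4, ny=3, column_split=(1, 1, 2))
    run = run_tissue(g, duration=10.0, snapshot_interval=2.0)
    assert np.allclose(run.times, [0, 2, 4, 6, 8, 10])
    assert run.snapshots.shape == (6, 3, 4)
    assert np.isfinite(run.snapshots).all()
    assert run.v_max.shape == (3, 4)


# ---------------------------------------------------------------------------
# drive classification (synthetic runs)
# ---------------------------------------------------------------------------

def _synthetic_run(snaps, n_pace=2):
    snaps = np.asarray(snaps, dtype=np.float32)
    ny, nx = snaps.shape[1:]
    g = build_geometry(n_pace, 1.0, nx=nx, ny=ny,
                       column_split=(n_pace, 1, nx - n_pace - 1))
    vmax = snaps.max(axis=0)
    return TissueRun(g, np.arange(len(snaps), dtype=float) * 100.0,
                     snaps, vmax)


def test_classify_stalemate():
    snaps = np.full((50, 4, 6), -80.0)
    assert classify_drive(_synthetic_run(snaps)) == "stalemate"


def test_classify_pacemaker_only():
    snaps = np.full((60, 4, 6), -80.0)
    # pacemaker columns spike periodically, the rest never exceeds -60
    for k0 in (10, 30, 50):
        snaps[k0:k0 + 2, :, :2] = 20.0
    assert classify_drive(_synthetic_run(snaps)) == "pacemaker_only"


def test_classify_full_drive():
    snaps = np.full((60, 4, 6), -80.0)
    for k0 in (10, 30, 50):
        snaps[k0:k0 + 2, :, :2] = 20.0   # pacemaker fires
        snaps[k0 + 2:k0 + 4, :, 2:] = 15.0  # wave reaches every other cell
    assert classify_drive(_synthetic_run(snaps)) == "full_drive"
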