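"""Pseudo-ECG operator: oracles, symmetries, convergence."""

import numpy as np
import pytest

from biopace.ecg import Electrode, default_electrode, ecg_trace, ecg_value
from biopace.scenarios import make_test_fixture
from biopace.tissue import TissueRun, build_geometry


def test_uniform_field_gives_zero():
    el = Electrode(x0=20.0, y0=1.0)
    assert ecg_value(np.full((5, 4), -86.0), el) == pytest.approx(0.0, abs=1e-14)


def test_matches_bruteforce_double_sum():
    """Vectorised kernel vs an explicit double loop, machine precision."""
    V = make_test_fixture("random_field", seed=1, shape=(5, 4))
    dx = 0.15
    el = Electrode(x0=(4 - 1) * dx + 15.0, y0=(5 - 1) * dx / 2)
    ny, nx = V.shape
    acc = 0.0
    for i in range(ny):
        for j in range(nx):
            # central differences inside, one-sided at the edges
            jm, jp = max(j - 1, 0), min(j + 1, nx - 1)
            im, ip = max(i - 1, 0), min(i + 1, ny - 1)
            dvdx = (V[i, jp] - V[i, jm]) / ((jp - jm) * dx)
            dvdy = (V[ip, j] - V[im, j]) / ((ip - im) * dx)
            rx = j * dx - el.x0
            ry = i * dx - el.y0
            acc += (rx * dvdx + ry * dvdy) / (rx**2 + ry**2) ** 1.5
    expect = acc * dx * dx
    assert ecg_value(V, el, dx) == pytest.approx(expect, rel=1e-12)


def test_mirror_symmetry():
    """Mirroring the field and the electrode leaves the signal unchanged."""
    V = make_test_fixture("random_field", seed=3, shape=(6, 5))
    dx = 0.15
    el = Electrode(x0=(5 - 1) * dx + 10.0, y0=(6 - 1) * dx / 2)
    el_mirror = Electrode(x0=(5 - 1) * dx - el.x0, y0=el.y0)
    assert ecg_value(V[:, ::-1], el_mirror, dx) == pytest.approx(
        ecg_value(V, el, dx), rel=1e-12)


def test_sigma_linearity():
    V = make_test_fixture("random_field", seed=5, shape=(6, 5))
    el = Electrode(x0=30.0, y0=0.3)
    assert ecg_value(V, el, sigma=2.0) == pytest.approx(
        2.0 * ecg_value(V, el, sigma=1.0), rel=1e-14)


def test_distance_attenuation_monotone():
    # a uniform-gradient (wavefront-like) field: the far-field signal
    # must decay monotonically as the electrode moves away
    x = np.arange(5) * 0.15
    V = np.tile(-86.0 + 40.0 * x, (6, 1))
    vals = [abs(ecg_value(V, Electrode(x0=(5 - 1) * 0.15 + d, y0=0.375)))
            for d in (10.0, 20.0, 40.0, 80.0, 100.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_electrode_inside_tissue_rejected():
    with pytest.raises(ValueError, match="inside"):
        ecg_value(np.zeros((5, 5)), Electrode(x0=0.3, y0=0.3))


def test_converges_on_gaussian_field():
    """The discretised sum approaches the continuum lead-field integral
    of a smooth Gaussian bump under grid refinement."""
    errors = []
    for nx, ny in ((31, 21), (61, 41), (121, 81)):
        dx = 3.0 / (nx - 1)  # fixed 3 x 2 mm physical patch
        fx = make_test_fixture("gaussian_field", nx=nx, ny=ny, dx=dx,
                               sigma_mm=0.5, xc=1.5, yc=1.0)
        el = Electrode(x0=3.0 + 10.0, y0=1.0)
        # quadrature of the exact integrand (analytic gradient)
        rx = fx["x"][None, :] - el.x0
        ry = fx["y"][:, None] - el.y0
        r3 = (rx**2 + ry**2) ** 1.5
        exact = ((rx * fx["dVdx"] + ry * fx["dVdy"]) / r3).sum() * dx * dx
        errors.append(abs(ecg_value(fx["V"], el, dx) - exact))
    assert errors[2] < errors[1] < errors[0]
    assert errors[2] < errors[0] / 4  # at least 2nd-order convergence


def test_trace_over_constant_snapshots_is_constant():
    g = build_geometry(1, 1.0, nx=6, ny=4, column_split=(1, 2, 3))
    snaps = np.tile(make_test_fixture("random_field", seed=2, shape=(4, 6)),
                    (5, 1, 1)).astype(np.float32)
    run = TissueRun(g, np.arange(5.0), snaps, snaps.max(axis=0))
    tr = ecg_trace(run)
    assert len(tr.signal) == 5
    assert np.allclose(tr.signal, tr.signal[0])
    assert tr.electrode == default_electrode(g)
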