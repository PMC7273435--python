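"""Pseudo-ECG of the 2D sheet at a virtual extracellular electrode.

The far-field signal is the lead-field integral

    ECG = sigma * sum_ij  [ (x - x0) dV/dx + (y - y0) dV/dy ] / r^3 * dx*dy,

with r the distance from grid point (x, y) to the electrode (x0, y0);
this is the standard unbounded-medium pseudo-ECG,
ECG = sigma * integral of grad(V) . r_vec / r^3 over the sheet, with
r_vec pointing from the electrode to the tissue point.  Under this
sign convention a depolarisation wave propagating towards the
electrode produces a positive deflection, and a region of elevated
diastolic potential on the far side produces a positive baseline.

Spatial gradients are central differences (one-sided at the sheet
edges); sigma is an arbitrary lumped conductivity, so the signal is in
arbitrary units.  The default electrode sits 15 mm beyond the right
edge of the tissue, vertically centred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue import TissueGeometry, TissueRun, DX_MM

__all__ = ["Electrode", "ECGTrace", "default_electrode", "ecg_value", "ecg_trace"]


@dataclass(frozen=True)
class Electrode:
    """Virtual electrode position in mm (tissue cell (i, j) sits at
    x = j*dx, y = i*dx)."""

    x0: float
    y0: float


def default_electrode(geometry: TissueGeometry, offset_mm: float = 15.0) -> Electrode:
    """Electrode ``offset_mm`` beyond the right tissue edge, mid-height."""
    x0 = (geometry.nx - 1) * geometry.dx + offset_mm
    y0 = (geometry.ny - 1) * geometry.dx / 2.0
    return Electrode(x0, y0)


@dataclass
class ECGTrace:
    """Pseudo-ECG time series (arbitrary units)."""

    t: np.ndarray
    signal: np.ndarray
    electrode: Electrode | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.shape != self.signal.shape:
            raise ValueError("t and signal must have equal length")


def _check_outside(V_shape, dx: float, electrode: Electrode) -> None:
    ny, nx = V_shape
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    r2 = (x[None, :] - electrode.x0) ** 2 + (y[:, None] - electrode.y0) ** 2
    if np.any(r2 < (0.5 * dx) ** 2):
        raise ValueError("electrode lies inside the tissue (singular kernel)")


def ecg_value(
    V: np.ndarray,
    electrode: Electrode,
    dx: float = DX_MM,
    sigma: float = 1.0,
) -> float:
    """Pseudo-ECG of a single voltage field snapshot."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2D field")
    _check_outside(V.shape, dx, electrode)
    ny, nx = V.shape
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    dVdy, dVdx = np.gradient(V, dx)  # central inside, one-sided at edges
    rx = x[None, :] - electrode.x0
    ry = y[:, None] - electrode.y0
    r3 = (rx ** 2 + ry ** 2) ** 1.5
    integrand = (rx * dVdx + ry * dVdy) / r3
    return float(sigma * integrand.sum() * dx * dx)


def ecg_trace(
    run: TissueRun,
    electrode: Electrode | None = None,
    sigma: float = 1.0,
) -> ECGTrace:
    """One pseudo-ECG sample per stored snapshot of a tissue run."""
    if electrode is None:
        electrode = default_electrode(run.geometry)
    sig = np.empty(len(run.times))
    for k in range(len(run.times)):
        sig[k] = ecg_value(run.snapshots[k], electrode, run.geometry.dx, sigma)
    return ECGTrace(run.times.copy(), sig, electrode)
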