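"""Action-potential feature extraction from voltage traces.

Detects spontaneous action potentials as upward threshold crossings
whose excursion (trough-to-peak) exceeds a minimum amplitude, then
measures cycle length, maximal upstroke velocity, peak potential and
maximum diastolic potential (MDP).

Detection defaults: threshold -40 mV, minimum amplitude 60 mV.  These
separate full APs from the damped subthreshold oscillations that a
near-threshold g_K1 produces.  A cell is "automatic" when the
analysis window contains at least 3 full APs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "APFeatures",
    "detect_cycles",
    "extract_features",
    "is_automatic",
    "UPSTROKE_THRESHOLD_MV",
    "MIN_AP_AMPLITUDE_MV",
    "MIN_AUTOMATIC_CYCLES",
]

UPSTROKE_THRESHOLD_MV = -40.0
MIN_AP_AMPLITUDE_MV = 60.0
MIN_AUTOMATIC_CYCLES = 3


@dataclass(frozen=True)
class APFeatures:
    """Quantitative features of a (possibly quiescent) voltage trace.

    ``period`` is the mean inter-upstroke interval in ms (NaN when
    fewer than 2 cycles were detected); ``dvdt_max`` the maximal
    upstroke velocity in V/s (mV/ms); ``mdp`` the most negative
    potential between APs in mV.
    """

    period: float
    dvdt_max: float
    peak_V: float
    mdp: float
    n_cycles: int

    @classmethod
    def quiescent(cls) -> "APFeatures":
        return cls(np.nan, np.nan, np.nan, np.nan, 0)


def _as_tv(trace):
    """Accept a VoltageTrace-like object or a (t, V) pair."""
    if hasattr(trace, "t") and hasattr(trace, "V"):
        return np.asarray(trace.t, float), np.asarray(trace.V, float)
    t, V = trace
    return np.asarray(t, float), np.asarray(V, float)


def detect_cycles(
    trace,
    threshold_mV: float = UPSTROKE_THRESHOLD_MV,
    min_amplitude_mV: float = MIN_AP_AMPLITUDE_MV,
) -> np.ndarray:
    """Times of AP upstrokes (upward crossings of ``threshold_mV``).

    A crossing counts only if the excursion it starts — from the
    preceding trough to the peak reached before V falls back below
    threshold — spans at least ``min_amplitude_mV``.  Multiple
    crossings within one suprathreshold excursion are deduplicated by
    construction.  Returns an empty array for constant or empty traces.
    """
    t, V = _as_tv(trace)
    if len(V) < 2:
        return np.array([])
    above = V >= threshold_mV
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1   # first index above
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1  # first index below
    times = []
    prev_down = 0
    for k in up:
        nxt = down[down > k]
        end = nxt[0] if len(nxt) else len(V)
        peak = V[k:end].max()
        trough = V[prev_down:k].min() if k > prev_down else V[k]
        if peak - trough >= min_amplitude_mV:
            times.append(t[k])
        prev_down = end
    return np.asarray(times)


def is_automatic(trace,
                 threshold_mV: float = UPSTROKE_THRESHOLD_MV,
                 min_amplitude_mV: float = MIN_AP_AMPLITUDE_MV,
                 min_cycles: int = MIN_AUTOMATIC_CYCLES) -> bool:
    """Whether the window shows sustained spontaneous firing."""
    return len(detect_cycles(trace, threshold_mV, min_amplitude_mV)) >= min_cycles


def extract_features(
    trace,
    threshold_mV: float = UPSTROKE_THRESHOLD_MV,
    min_amplitude_mV: float = MIN_AP_AMPLITUDE_MV,
) -> APFeatures:
    """Measure period, dV/dt_max, peak potential and MDP.

    The caller selects the analysis window (the settling transient
    should already be discarded).  The period is the mean over all
    complete inter-upstroke intervals; the derivative is a central
    finite difference on the recorded grid, restricted to detected AP
    upstrokes; the MDP is the most negative V between consecutive
    upstrokes.
    """
    t, V = _as_tv(trace)
    upstrokes = detect_cycles((t, V), threshold_mV, min_amplitude_mV)
    n = len(upstrokes)
    if n == 0:
        if len(V) == 0:
            return APFeatures.quiescent()
        return APFeatures(np.nan, np.nan, float(V.max()), float(V.min()), 0)

    period = float(np.mean(np.diff(upstrokes))) if n >= 2 else np.nan

    dVdt = np.gradient(V, t)  # mV/ms == V/s
    # restrict to the depolarisation phases: around each upstroke, from
    # the previous trough up to the AP peak
    idx_up = np.searchsorted(t, upstrokes)
    dvdt_max = -np.inf
    for k in idx_up:
        lo = max(0, k - 1)
        while lo > 0 and V[lo - 1] <= V[lo]:
            lo -= 1
        hi = k
        while hi < len(V) - 1 and V[hi + 1] >= V[hi]:
            hi += 1
        dvdt_max = max(dvdt_max, float(dVdt[lo:hi + 1].max()))

    peak_V = float(V.max())
    if n >= 2:
        i0, i1 = idx_up[0], idx_up[-1]
        mdp = float(V[i0:i1].min())
    else:
        mdp = float(V.min())
    return APFeatures(period, dvdt_max, peak_V, mdp, n)
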