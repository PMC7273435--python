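"""Single-cell pacemaker simulations and conductance scans.

The central experiment: depressing the inward-rectifier conductance
g_K1 from its normal 5.405 nS/pF to 0.05 nS/pF (0.93% of normal)
converts the quiescent ventricular myocyte into a spontaneously
beating pacemaker cell.  This module runs such cells, scans a chosen
maximal conductance over a range while recording action-potential
features, and locates the largest g_K1 fraction at which automaticity
survives by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import tnnp06
from .tnnp06 import (
    BlowUpError,
    CellParameters,
    CellState,
    CURRENT_NAMES,
    N_CURRENTS,
)
from .features import APFeatures, extract_features, is_automatic

__all__ = [
    "VoltageTrace",
    "ScanResult",
    "run_cell",
    "scan_conductance",
    "find_automaticity_threshold",
    "PACEMAKER_G_K1",
    "TRANSIENT_MS",
    "SCAN_RANGES",
]

#: g_K1 used to convert a myocyte into a pacing cell (nS/pF)
PACEMAKER_G_K1 = 0.05

#: default production run length and settling window (ms)
PRODUCTION_DURATION = 20_000.0
TRANSIENT_MS = 10_000.0

#: settling time to reach the concentration steady state (ms).  The slow
#: intracellular Na+/K+ balance of a spontaneously beating cell drifts for
#: minutes of simulated time; the pacing period converges to <0.3% only
#: after ~300 s.
STABLE_SETTLE_MS = 300_000.0

#: conductance scan ranges (min, max) studied in the pacing experiments
SCAN_RANGES = {
    "g_bCa": (0.0, 12e-4),
    "g_Na": (0.0, 30.0),
    "g_CaL": (0.0, 8e-5),
    "g_to": (0.0, 0.08),
}


@dataclass
class VoltageTrace:
    """Membrane-potential time series from a single-cell run.

    ``t`` in ms on a uniform grid, ``V`` in mV; ``currents`` optionally
    maps each current name to its trace in pA/pF.
    """

    t: np.ndarray
    V: np.ndarray
    currents: dict[str, np.ndarray] | None = None
    params: CellParameters | None = None
    final_state: CellState | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.shape != self.V.shape:
            raise ValueError("t and V must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if isinstance(self.final_state, np.ndarray):
            self.final_state = CellState.from_array(self.final_state)

    @property
    def stride(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    def window(self, t_min: float, t_max: float | None = None) -> "VoltageTrace":
        """Sub-trace with t in [t_min, t_max]."""
        if t_max is None:
            t_max = np.inf
        sel = (self.t >= t_min) & (self.t <= t_max)
        cur = None
        if self.currents is not None:
            cur = {k: v[sel] for k, v in self.currents.items()}
        return VoltageTrace(self.t[sel], self.V[sel], cur, self.params)


@dataclass
class ScanResult:
    """Outcome of a one-parameter conductance scan."""

    parameter: str
    values: np.ndarray
    features: list[APFeatures]
    automatic: np.ndarray  # bool per value
    errors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.values) > 0):
            raise ValueError("scan values must be strictly increasing")
        if len(self.features) != len(self.values):
            raise ValueError("one feature record required per scan value")
        self.automatic = np.asarray(self.automatic, dtype=bool)

    @property
    def periods(self) -> np.ndarray:
        return np.array([f.period for f in self.features])

    def to_frame(self):
        import pandas as pd

        rows = []
        for v, feat, auto in zip(self.values, self.features, self.automatic):
            rows.append({
                "value": v, "automatic": auto, "period_ms": feat.period,
                "dvdt_max_V_per_s": feat.dvdt_max, "peak_V_mV": feat.peak_V,
                "mdp_mV": feat.mdp, "n_cycles": feat.n_cycles,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# jitted time loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_loop(s, p, dt, n_steps, rec_every, out_V, record_currents, out_cur):
    """Integrate ``n_steps`` steps, sampling every ``rec_every`` steps.

    Sample k holds the state at t = k * rec_every * dt (sample 0 is the
    initial state).  Returns the step index of failure, or -1.
    """
    cur = np.empty(N_CURRENTS)
    out_V[0] = s[0]
    if record_currents:
        tnnp06._currents(s, p, cur)
        for c in range(N_CURRENTS):
            out_cur[0, c] = cur[c]
    k = 1
    for i in range(1, n_steps + 1):
        tnnp06._step_cell(s, p, dt, 0.0, 0.0, cur)
        if i % 1000 == 0 and not tnnp06._state_ok(s):
            return i
        if i % rec_every == 0:
            out_V[k] = s[0]
            if record_currents:
                tnnp06._currents(s, p, cur)
                for c in range(N_CURRENTS):
                    out_cur[k, c] = cur[c]
            k += 1
    return -1


def run_cell(
    params: CellParameters | None = None,
    duration: float = PRODUCTION_DURATION,
    dt: float = 0.02,
    record_stride: float = 0.1,
    record_currents: bool = False,
    initial_state: CellState | None = None,
    settle_ms: float = 0.0,
    I_stim: float = 0.0,
) -> VoltageTrace:
    """Integrate one myocyte for ``duration`` ms with no external stimulus.

    Parameters
    ----------
    params
        Cell parameters; defaults to the normal endocardial cell.
    duration, dt
        Simulated (recorded) time and integration step, ms.  Production
        feature measurements use duration >= 20,000 ms at dt = 0.02 ms.
    record_stride
        Output sampling interval, ms (must be a multiple of dt);
        0.1 ms resolves the upstroke velocity of the slow pacemaker AP.
    record_currents
        Also record the twelve membrane currents at each sample.
    settle_ms
        Unrecorded pre-integration time; use STABLE_SETTLE_MS to measure
        on the concentration steady state (the recorded trace then starts
        at the settled state, with t = 0 at the end of settling).

    Returns
    -------
    VoltageTrace
        With ``final_state`` attached for run continuation.
    """
    if params is None:
        params = CellParameters()
    if I_stim != 0.0:
        raise ValueError("the pacemaker experiments use I_stim = 0")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be > 0")
    rec_every = max(1, round(record_stride / dt))
    n_steps = round(duration / dt)
    n_samples = n_steps // rec_every + 1

    s = (initial_state or tnnp06.RESTING_STATE).to_array()
    p = params.to_array()
    if settle_ms > 0:
        n_settle = round(settle_ms / dt)
        dummy = np.empty(2)
        fail = _run_loop(s, p, dt, n_settle, n_settle, dummy,
                         False, np.empty((1, N_CURRENTS)))
        if fail >= 0:
            raise BlowUpError(fail * dt, f"during settling; params: {params}")
    out_V = np.empty(n_samples)
    out_cur = np.empty((n_samples if record_currents else 1, N_CURRENTS))
    fail = _run_loop(s, p, dt, n_steps, rec_every, out_V,
                     record_currents, out_cur)
    if fail >= 0:
        raise BlowUpError(fail * dt, f"params: {params}")
    t = np.arange(n_samples) * (rec_every * dt)
    currents = None
    if record_currents:
        currents = {name: out_cur[:, i] for i, name in enumerate(CURRENT_NAMES)}
    return VoltageTrace(t, out_V, currents, params, CellState.from_array(s))


def scan_conductance(
    name: str,
    values,
    base_params: CellParameters | None = None,
    duration: float = PRODUCTION_DURATION,
    dt: float = 0.02,
    transient_ms: float = TRANSIENT_MS,
    settle_ms: float = STABLE_SETTLE_MS,
) -> ScanResult:
    """Run one simulation per conductance value and extract AP features.

    ``name`` is a CellParameters field (e.g. ``"g_Na"``); each value is
    settled to the concentration steady state (``settle_ms``) before the
    recorded window, and features are measured on the post-transient part
    of that window.  A failed run is recorded in ``errors`` (with
    quiescent features) and the scan continues.
    """
    if base_params is None:
        base_params = CellParameters(g_K1=PACEMAKER_G_K1)
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("scan values must be non-negative")
    feats: list[APFeatures] = []
    auto = np.zeros(len(values), dtype=bool)
    errors: dict[int, str] = {}
    for i, v in enumerate(values):
        p = base_params.replace(**{name: float(v)})
        try:
            trace = run_cell(p, duration=duration, dt=dt, settle_ms=settle_ms)
        except BlowUpError as exc:  # keep scanning
            errors[i] = str(exc)
            feats.append(APFeatures.quiescent())
            continue
        w = trace.window(transient_ms)
        feats.append(extract_features(w))
        auto[i] = is_automatic(w)
    return ScanResult(name, values, feats, auto, errors)


def find_automaticity_threshold(
    base_params: CellParameters | None = None,
    lo_fraction: float = 0.0,
    hi_fraction: float = 0.2,
    tol: float = 0.001,
    duration: float = PRODUCTION_DURATION,
    dt: float = 0.02,
    transient_ms: float = TRANSIENT_MS,
) -> float:
    """Largest g_K1 fraction (percent of normal) with sustained automaticity.

    Bisects the g_K1 scaling factor between ``lo_fraction`` (automatic)
    and ``hi_fraction`` (quiescent); classification requires >= 3 full
    APs in the post-transient window.  ``tol`` is in fraction-of-normal
    units (0.001 = 0.1 percentage point).

    Returns the boundary as a percentage of the normal g_K1.
    """
    if base_params is None:
        base_params = CellParameters()
    g_normal = type(base_params)().g_K1

    def automatic(frac: float) -> bool:
        p = base_params.replace(g_K1=frac * g_normal)
        trace = run_cell(p, duration=duration, dt=dt, record_stride=0.5)
        return is_automatic(trace.window(transient_ms))

    lo_auto = automatic(lo_fraction)
    hi_auto = automatic(hi_fraction)
    if not lo_auto or hi_auto:
        raise ValueError(
            "invalid bracket: need automaticity at lo_fraction "
            f"(got {lo_auto}) and quiescence at hi_fraction (got {hi_auto})")
    lo, hi = lo_fraction, hi_fraction
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if automatic(mid):
            lo = mid
        else:
            hi = mid
    return 100.0 * lo
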