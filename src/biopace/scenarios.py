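"""Experiment registry and synthetic test fixtures.

Every experiment configuration of the pacemaker analysis is constructible by name,
so the whole pipeline runs without external data: the base pacemaker
cell, the four conductance scans, the g_K1 automaticity-threshold
search, the tissue driving cases and the pseudo-ECG readout.  Each 2D
scenario has a ``*_small`` twin (half-size grid, 3 s) cheap enough for
routine testing; the full-size variants use the full experiment geometry
(100 x 50 cells, >= 20 s).

The model is deterministic; scenarios carry no randomness.  The only
seeded object is the ``random_field`` test fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .single_cell import (
    PACEMAKER_G_K1,
    PRODUCTION_DURATION,
    STABLE_SETTLE_MS,
    SCAN_RANGES,
    find_automaticity_threshold,
    run_cell,
    scan_conductance,
)
from .tnnp06 import CellParameters
from .tissue import build_geometry, run_tissue, DX_MM

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario", "run_scenario",
           "make_test_fixture"]

#: default scale factor for the boosted-current cases: the four
#: depolarising currents are increased by 200% (factor 3) by default;
#: use 2.0 for a plain doubling instead.
DEFAULT_BOOST = 3.0
_BOOSTED = ("g_bCa", "g_bNa", "g_Na", "g_CaL")


@dataclass
class Scenario:
    """A fully specified, deterministic, runnable experiment."""

    name: str
    kind: str  # "single_cell" | "scan" | "threshold" | "tissue" | "ecg"
    description: str
    cell_overrides: dict = dc_field(default_factory=dict)
    scan: dict = dc_field(default_factory=dict)
    geometry: dict = dc_field(default_factory=dict)
    tissue: dict = dc_field(default_factory=dict)
    solver: dict = dc_field(default_factory=dict)
    expected: str = ""


def _scan_values(name: str, n: int = 7) -> np.ndarray:
    lo, hi = SCAN_RANGES[name]
    return np.linspace(lo, hi, n)


def _single(name, desc, overrides, expected):
    return Scenario(
        name=name, kind="single_cell", description=desc,
        cell_overrides=overrides,
        solver=dict(duration=PRODUCTION_DURATION, dt=0.02,
                    record_stride=0.1, settle_ms=STABLE_SETTLE_MS,
                    record_currents=True),
        expected=expected)


def _scan(name, param, desc):
    return Scenario(
        name=name, kind="scan", description=desc,
        cell_overrides={"g_K1": PACEMAKER_G_K1},
        scan=dict(parameter=param, values=_scan_values(param).tolist()),
        solver=dict(duration=PRODUCTION_DURATION, dt=0.02,
                    settle_ms=STABLE_SETTLE_MS),
        expected="pacing features vs conductance")


def _tissue(name, desc, n_pace, d_frac, expected, *, nx=100, ny=50,
            duration=20_000.0, tissue_scale=None, pacemaker_scale=None):
    return Scenario(
        name=name, kind="tissue", description=desc,
        geometry=dict(n_pacemaker_columns=n_pace,
                      pacemaker_D_fraction=d_frac, nx=nx, ny=ny),
        tissue=dict(tissue_scale=tissue_scale or {},
                    pacemaker_scale=pacemaker_scale or {}),
        solver=dict(duration=duration, dt=0.02, snapshot_interval=1.0),
        expected=expected)


def _registry() -> dict[str, Scenario]:
    reg: dict[str, Scenario] = {}

    reg["fig3_base"] = _single(
        "fig3_base",
        "Pacemaker cell (g_K1 = 0.05 nS/pF): spontaneous AP and all "
        "twelve membrane currents",
        {"g_K1": PACEMAKER_G_K1},
        "periodic spontaneous APs, slow then rapid depolarisation")
    reg["quiescent_base"] = _single(
        "quiescent_base",
        "Unmodified myocyte: no stimulus, no automaticity",
        {},
        "resting near -86 mV")

    reg["fig4_gbca_scan"] = _scan("fig4_gbca_scan", "g_bCa",
                                  "Background Ca2+ conductance scan, 0-12e-4 nS/pF")
    reg["fig5_gna_scan"] = _scan("fig5_gna_scan", "g_Na",
                                 "Fast Na+ conductance scan, 0-30 nS/pF")
    reg["fig6_gcal_scan"] = _scan("fig6_gcal_scan", "g_CaL",
                                  "L-type Ca2+ scale scan, 0-8e-5")
    reg["fig7_gto_scan"] = _scan("fig7_gto_scan", "g_to",
                                 "Transient-outward conductance scan, 0-0.08 nS/pF")

    reg["threshold"] = Scenario(
        name="threshold", kind="threshold",
        description="Bisection for the largest g_K1 fraction with "
                    "sustained automaticity",
        solver=dict(lo_fraction=0.0, hi_fraction=0.2, tol=0.001,
                    duration=PRODUCTION_DURATION),
        expected="boundary as % of normal g_K1")

    reg["case1"] = _tissue(
        "case1", "All 25 endocardial columns paced, normal currents and "
        "coupling", 25, 1.0, "size-sensitive (see docs/methods.md)")
    reg["case2"] = _tissue(
        "case2", "Case 1 plus boosted depolarising currents inside the "
        "pacemaker only", 25, 1.0,
        "size- and boost-sensitive (see docs/methods.md)",
        pacemaker_scale={k: DEFAULT_BOOST for k in _BOOSTED})
    reg["global_boost"] = _tissue(
        "global_boost", "Boosted depolarising currents in the whole "
        "tissue, 25 pacing columns", 25, 1.0, "full_drive",
        tissue_scale={k: DEFAULT_BOOST for k in _BOOSTED})
    reg["weak_coupling"] = _tissue(
        "weak_coupling", "23 pacing columns with coupling reduced to "
        "0.09 of normal inside the pacemaker", 23, 0.09, "full_drive")

    # half-size, 3 s twins for routine testing (12/18/20 column split)
    small = dict(nx=50, ny=25, duration=3000.0)
    reg["case1_small"] = _tissue(
        "case1_small", "Half-size Case 1", 12, 1.0, "stalemate", **small)
    reg["case2_small"] = _tissue(
        "case2_small", "Half-size Case 2", 12, 1.0, "full_drive",
        pacemaker_scale={k: DEFAULT_BOOST for k in _BOOSTED}, **small)
    reg["global_boost_small"] = _tissue(
        "global_boost_small", "Half-size whole-tissue boost", 12, 1.0,
        "full_drive", tissue_scale={k: DEFAULT_BOOST for k in _BOOSTED},
        **small)
    reg["weak_coupling_small"] = _tissue(
        "weak_coupling_small", "Half-size weak-coupling pacemaker", 11,
        0.09, "full_drive", **small)

    for base in ("weak_coupling", "weak_coupling_small"):
        src = reg[base]
        ecg_name = "ecg" if base == "weak_coupling" else "ecg_small"
        reg[ecg_name] = Scenario(
            name=ecg_name, kind="ecg",
            description="Pseudo-ECG of the driven (weak-coupling) tissue",
            geometry=dict(src.geometry), tissue=dict(src.tissue),
            solver=dict(src.solver), expected="positive QRS and T waves")

    reg["toy_grid_4x4"] = _tissue(
        "toy_grid_4x4", "Miniature 4x4 tissue for operator oracles",
        2, 1.0, "n/a", nx=4, ny=4, duration=100.0)
    reg["toy_grid_4x4"].geometry["column_split"] = (2, 1, 1)
    return reg


_REGISTRY = _registry()
SCENARIO_NAMES = tuple(sorted(_REGISTRY))


def make_scenario(name: str) -> Scenario:
    """Look up a named experiment; error lists the registry."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; registered: {', '.join(SCENARIO_NAMES)}"
        ) from None


def run_scenario(scenario: Scenario | str, **solver_overrides):
    """Execute a scenario and return its natural result object.

    single_cell -> VoltageTrace; scan -> ScanResult; threshold -> float
    (percent of normal g_K1); tissue -> TissueRun; ecg -> (TissueRun,
    ECGTrace).  ``solver_overrides`` tweak durations etc. for quick runs.
    """
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    solver = {**scenario.solver, **solver_overrides}
    if scenario.kind == "single_cell":
        params = CellParameters(**scenario.cell_overrides)
        return run_cell(params, **solver)
    if scenario.kind == "scan":
        base = CellParameters(**scenario.cell_overrides)
        return scan_conductance(scenario.scan["parameter"],
                                scenario.scan["values"], base, **solver)
    if scenario.kind == "threshold":
        return find_automaticity_threshold(**solver)
    if scenario.kind in ("tissue", "ecg"):
        geom = build_geometry(**scenario.geometry)
        run = run_tissue(geom, scenario=dict(name=scenario.name),
                         **scenario.tissue, **solver)
        if scenario.kind == "ecg":
            from .ecg import ecg_trace
            return run, ecg_trace(run)
        return run
    raise ValueError(f"unknown scenario kind {scenario.kind!r}")


# ---------------------------------------------------------------------------
# synthetic toy fixtures with analytically known features
# ---------------------------------------------------------------------------

def make_test_fixture(kind: str, **kwargs):
    """Deterministic toy inputs for feature/operator tests.

    kinds: ``sawtooth_trace`` (known period and ramp slope),
    ``pulse_train`` (known upstroke times), ``gaussian_field`` (closed-
    form gradient), ``random_field`` (seeded, reproducible).
    """
    if kind == "sawtooth_trace":
        period = kwargs.get("period_ms", 500.0)
        n_cycles = kwargs.get("n_cycles", 5)
        ramp_v_per_s = kwargs.get("ramp_v_per_s", 10.0)
        stride = kwargs.get("stride_ms", 0.1)
        lo, hi = -90.0, 10.0
        rise = (hi - lo) / ramp_v_per_s  # ms
        t = np.arange(0.0, n_cycles * period, stride)
        phase = t % period
        V = np.where(phase < rise,
                     lo + ramp_v_per_s * phase,
                     hi - (hi - lo) * (phase - rise) / (period - rise))
        return t, V
    if kind == "pulse_train":
        n = kwargs.get("n_pulses", 5)
        period = kwargs.get("period_ms", 300.0)
        width = kwargs.get("width_ms", 50.0)
        stride = kwargs.get("stride_ms", 0.5)
        t = np.arange(0.0, n * period, stride)
        phase = t % period
        V = np.where((phase >= 100.0) & (phase < 100.0 + width), 20.0, -86.0)
        return t, V
    if kind == "gaussian_field":
        ny = kwargs.get("ny", 20)
        nx = kwargs.get("nx", 30)
        dx = kwargs.get("dx", DX_MM)
        sig = kwargs.get("sigma_mm", 0.6)
        amp = kwargs.get("amplitude_mv", 100.0)
        xc = kwargs.get("xc", (nx - 1) * dx / 2)
        yc = kwargs.get("yc", (ny - 1) * dx / 2)
        x = np.arange(nx) * dx
        y = np.arange(ny) * dx
        X, Y = np.meshgrid(x, y)
        V = amp * np.exp(-((X - xc) ** 2 + (Y - yc) ** 2) / (2 * sig ** 2))
        dVdx = -(X - xc) / sig ** 2 * V
        dVdy = -(Y - yc) / sig ** 2 * V
        return dict(V=V, dVdx=dVdx, dVdy=dVdy, dx=dx, x=x, y=y)
    if kind == "random_field":
        seed = kwargs.get("seed", 1)
        shape = kwargs.get("shape", (6, 5))
        rng = np.random.default_rng(seed)
        return rng.normal(-60.0, 30.0, size=shape)
    raise ValueError(f"unknown fixture kind {kind!r}")
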