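"""2D heterogeneous monodomain tissue with a biological-pacemaker region.

The tissue is a rectangular sheet of TNNP06 myocytes,

    dV/dt = -(I_ion + I_stim)/C_m + div(D grad V),

discretised on a uniform grid (dx = 0.15 mm) with a 5-point stencil in
divergence (flux) form, face diffusivities as arithmetic means of the
two adjacent cells, and no-flux boundaries.  The default geometry is
100 columns x 50 rows: 25 endocardial columns on the left, 35
midmyocardial in the middle, 40 epicardial on the right.  A pacemaker
region (the leftmost n columns) has its cells converted to pacing
cells (g_K1 = 0.05 nS/pF) and optionally its gap-junction coupling D
reduced, which protects the pacemaker from the hyperpolarising load of
the surrounding quiescent tissue.

Note the unit bookkeeping: D is stated in cm^2/s (normal 0.154); the
diffusion term is D * (5-point stencil) / dx^2 in mV/ms, i.e.
0.0154 mm^2/ms / (0.15 mm)^2 ~ 0.684 /ms at normal coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import tnnp06
from .tnnp06 import BlowUpError, CellParameters, CellState, N_CURRENTS, N_PARAMS
from .features import detect_cycles
from .single_cell import PACEMAKER_G_K1

__all__ = [
    "TissueGeometry",
    "TissueRun",
    "build_geometry",
    "laplacian_term",
    "run_tissue",
    "classify_drive",
    "D_NORMAL_CM2_S",
    "DX_MM",
]

D_NORMAL_CM2_S = 0.154
DX_MM = 0.15
_CM2S_TO_MM2MS = 0.1  # 1 cm^2/s = 0.1 mm^2/ms

_TYPE_CODES = {"endocardial": 0, "midmyocardial": 1, "epicardial": 2}
_TYPE_NAMES = {v: k for k, v in _TYPE_CODES.items()}


@dataclass
class TissueGeometry:
    """Grid dimensions, per-cell type labels, pacemaker mask, D map.

    ``cell_type_map`` holds codes 0/1/2 for endo/mid/epi, shape (ny, nx);
    ``pacemaker_mask`` flags pacing cells; ``D`` is the per-cell diffusion
    coefficient in cm^2/s; ``dx`` the lattice spacing in mm.
    """

    nx: int
    ny: int
    cell_type_map: np.ndarray
    pacemaker_mask: np.ndarray
    D: np.ndarray
    dx: float = DX_MM

    def __post_init__(self):
        self.cell_type_map = np.asarray(self.cell_type_map, dtype=np.int8)
        self.pacemaker_mask = np.asarray(self.pacemaker_mask, dtype=bool)
        self.D = np.asarray(self.D, dtype=float)
        shape = (self.ny, self.nx)
        for name in ("cell_type_map", "pacemaker_mask", "D"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        if np.any(self.D < 0):
            raise ValueError("D must be >= 0 everywhere")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny


def _column_split(nx: int) -> tuple[int, int, int]:
    """Endo/mid/epi column counts in the 25:35:40 proportion."""
    n_endo = round(nx * 0.25)
    n_mid = round(nx * 0.35)
    return n_endo, n_mid, nx - n_endo - n_mid


def build_geometry(
    n_pacemaker_columns: int,
    pacemaker_D_fraction: float = 1.0,
    nx: int = 100,
    ny: int = 50,
    column_split: tuple[int, int, int] | None = None,
    D_normal: float = D_NORMAL_CM2_S,
    dx: float = DX_MM,
) -> TissueGeometry:
    """Construct the transmural slab with a left-edge pacemaker region.

    The leftmost ``n_pacemaker_columns`` are flagged as pacing cells and
    get ``pacemaker_D_fraction`` x the normal diffusion coefficient
    (e.g. 23 columns at fraction 0.09 is the weak-coupling pacemaker).
    The pacemaker may only occupy endocardial columns.
    """
    if column_split is None:
        column_split = _column_split(nx)
    n_endo, n_mid, n_epi = column_split
    if n_endo + n_mid + n_epi != nx:
        raise ValueError("column split must sum to nx")
    if not 0 <= n_pacemaker_columns <= n_endo:
        raise ValueError(
            f"pacemaker must stay within the {n_endo} endocardial columns, "
            f"got {n_pacemaker_columns}")
    types = np.empty((ny, nx), dtype=np.int8)
    types[:, :n_endo] = 0
    types[:, n_endo:n_endo + n_mid] = 1
    types[:, n_endo + n_mid:] = 2
    mask = np.zeros((ny, nx), dtype=bool)
    mask[:, :n_pacemaker_columns] = True
    D = np.full((ny, nx), D_normal)
    D[mask] = pacemaker_D_fraction * D_normal
    return TissueGeometry(nx, ny, types, mask, D, dx)


@dataclass
class TissueRun:
    """Voltage-field snapshots and summary arrays from a tissue run."""

    geometry: TissueGeometry
    times: np.ndarray              # snapshot times, ms
    snapshots: np.ndarray          # (nt, ny, nx) mV, float32
    v_max: np.ndarray              # per-cell max V over the whole run
    scenario: dict = field(default_factory=dict)

    def cell_trace(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(t, V) of cell (row i, column j) at snapshot resolution."""
        return self.times, self.snapshots[:, i, j].astype(float)


# ---------------------------------------------------------------------------
# diffusion operator
# ---------------------------------------------------------------------------

def laplacian_term(V: np.ndarray, D: np.ndarray, dx: float = DX_MM) -> np.ndarray:
    """Diffusion contribution div(D grad V) in mV/ms.

    5-point stencil in divergence form: the flux across each face uses
    the arithmetic mean of the two adjacent cells' D (cm^2/s); no-flux
    boundaries (mirrored neighbours carry zero flux).  ``dx`` in mm.
    """
    V = np.asarray(V, dtype=float)
    D = np.asarray(D, dtype=float)
    if V.shape != D.shape:
        raise ValueError(f"V {V.shape} and D {D.shape} shapes differ")
    Dmm = D * _CM2S_TO_MM2MS
    out = np.zeros_like(V)
    # east/west faces (along columns axis=1)
    face = 0.5 * (Dmm[:, 1:] + Dmm[:, :-1]) * (V[:, 1:] - V[:, :-1])
    out[:, :-1] += face
    out[:, 1:] -= face
    # north/south faces (axis=0)
    face = 0.5 * (Dmm[1:, :] + Dmm[:-1, :]) * (V[1:, :] - V[:-1, :])
    out[:-1, :] += face
    out[1:, :] -= face
    return out / (dx * dx)


@njit(cache=True, fastmath=True)
def _tissue_loop(S, P, DE, DS, ny, nx, dt, n_steps, snap_every,
                 snaps, vmax, check_every):
    """Jitted monodomain time loop.

    ``S``: (ny*nx, N_STATE) states; ``P``: (ny*nx, N_PARAMS); ``DE[i,j]``
    is the face conductance (1/ms) between (i,j) and (i,j+1) (0 on the
    right edge), ``DS[i,j]`` between (i,j) and (i+1,j).  Snapshot s
    holds the state at step s*snap_every (s=0 is the initial state).
    Returns the failing step index, or -1.
    """
    nc = ny * nx
    lap = np.empty(nc)
    cur = np.empty(N_CURRENTS)
    k = 0
    for i in range(ny):
        for j in range(nx):
            snaps[0, i, j] = S[i * nx + j, 0]
            v = S[i * nx + j, 0]
            if v > vmax[i * nx + j]:
                vmax[i * nx + j] = v
    for step in range(1, n_steps + 1):
        for i in range(ny):
            base = i * nx
            for j in range(nx):
                c = base + j
                acc = 0.0
                v = S[c, 0]
                if j < nx - 1:
                    acc += DE[i, j] * (S[c + 1, 0] - v)
                if j > 0:
                    acc -= DE[i, j - 1] * (v - S[c - 1, 0])
                if i < ny - 1:
                    acc += DS[i, j] * (S[c + nx, 0] - v)
                if i > 0:
                    acc -= DS[i - 1, j] * (v - S[c - nx, 0])
                lap[c] = acc
        for c in range(nc):
            tnnp06._step_cell(S[c], P[c], dt, 0.0, lap[c], cur)
            v = S[c, 0]
            if v > vmax[c]:
                vmax[c] = v
        if step % check_every == 0:
            for c in range(nc):
                if not tnnp06._state_ok(S[c]):
                    return step
        if step % snap_every == 0:
            k += 1
            for i in range(ny):
                for j in range(nx):
                    snaps[k, i, j] = S[i * nx + j, 0]
    return -1


def _cell_params_field(
    geometry: TissueGeometry,
    tissue_overrides: dict | None,
    tissue_scale: dict | None,
    pacemaker_overrides: dict | None,
    pacemaker_scale: dict | None,
) -> np.ndarray:
    """Per-cell parameter vectors from type defaults plus overrides."""
    P = np.empty((geometry.n_cells, N_PARAMS))
    cache: dict[tuple, np.ndarray] = {}
    types = geometry.cell_type_map.ravel()
    pace = geometry.pacemaker_mask.ravel()
    for c in range(geometry.n_cells):
        key = (int(types[c]), bool(pace[c]))
        if key not in cache:
            p = CellParameters.for_cell_type(_TYPE_NAMES[key[0]])
            if tissue_overrides:
                p = p.replace(**tissue_overrides)
            if tissue_scale:
                p = p.replace(**{k: getattr(p, k) * f
                                 for k, f in tissue_scale.items()})
            if key[1]:
                if pacemaker_overrides:
                    p = p.replace(**pacemaker_overrides)
                if pacemaker_scale:
                    p = p.replace(**{k: getattr(p, k) * f
                                     for k, f in pacemaker_scale.items()})
            cache[key] = p.to_array()
        P[c] = cache[key]
    return P


def run_tissue(
    geometry: TissueGeometry,
    duration: float,
    dt: float = 0.02,
    snapshot_interval: float = 1.0,
    tissue_overrides: dict | None = None,
    tissue_scale: dict | None = None,
    pacemaker_overrides: dict | None = None,
    pacemaker_scale: dict | None = None,
    initial_state: CellState | None = None,
    scenario: dict | None = None,
) -> TissueRun:
    """Integrate the monodomain sheet with I_stim = 0 everywhere.

    Every cell runs its own TNNP06 reaction term (endo/mid/epi defaults
    by the geometry's type map); pacemaker-flagged cells get
    ``pacemaker_overrides`` (default: g_K1 = 0.05 nS/pF).  ``tissue_*``
    apply to all cells, e.g. ``tissue_scale={"g_Na": 3.0}`` for the
    whole-tissue current boosts.  All cells start from ``initial_state``
    (published resting state by default).

    Raises BlowUpError on instability, with the failure time; the
    explicit scheme requires dt < dx^2 / (4 D_max) (checked).
    """
    if pacemaker_overrides is None:
        pacemaker_overrides = {"g_K1": PACEMAKER_G_K1}
    d_max = float(geometry.D.max()) * _CM2S_TO_MM2MS
    if d_max > 0 and dt >= geometry.dx ** 2 / (4.0 * d_max):
        raise ValueError(
            f"dt = {dt} ms violates the CFL bound "
            f"{geometry.dx ** 2 / (4.0 * d_max):.4f} ms")

    ny, nx = geometry.ny, geometry.nx
    s0 = (initial_state or tnnp06.RESTING_STATE).to_array()
    S = np.tile(s0, (ny * nx, 1))
    P = _cell_params_field(geometry, tissue_overrides, tissue_scale,
                           pacemaker_overrides, pacemaker_scale)

    # face conductances in 1/ms (already divided by dx^2)
    Dmm = geometry.D * _CM2S_TO_MM2MS / geometry.dx ** 2
    DE = np.zeros((ny, nx))
    DE[:, :-1] = 0.5 * (Dmm[:, :-1] + Dmm[:, 1:])
    DS = np.zeros((ny, nx))
    DS[:-1, :] = 0.5 * (Dmm[:-1, :] + Dmm[1:, :])

    snap_every = max(1, round(snapshot_interval / dt))
    n_steps = round(duration / dt)
    n_snaps = n_steps // snap_every + 1
    snaps = np.empty((n_snaps, ny, nx), dtype=np.float32)
    vmax = np.full(ny * nx, -np.inf)
    fail = _tissue_loop(S, P, DE, DS, ny, nx, dt, n_steps, snap_every,
                        snaps, vmax, 500)
    if fail >= 0:
        bad = [int(c) for c in range(ny * nx)
               if not tnnp06._state_ok(S[c])][:1]
        where = f"cell (i={bad[0] // nx}, j={bad[0] % nx})" if bad else "unknown cell"
        raise BlowUpError(fail * dt, where)
    times = np.arange(n_snaps) * (snap_every * dt)
    meta = dict(scenario or {})
    meta.setdefault("duration_ms", duration)
    meta.setdefault("dt_ms", dt)
    return TissueRun(geometry, times, snaps, vmax.reshape(ny, nx), meta)


def classify_drive(
    run: TissueRun,
    threshold_mV: float = -40.0,
    full_drive_mV: float = 0.0,
) -> str:
    """Classify the driving outcome of a tissue run.

    Returns one of:

    - ``"stalemate"``: no cell ever crosses -40 mV (the pacemaker is
      clamped by the surrounding tissue);
    - ``"full_drive"``: every cell exceeds 0 mV at least once in every
      detected pacing cycle (the wave traverses the whole sheet);
    - ``"pacemaker_only"``: anything in between.
    """
    if run.v_max.max() < threshold_mV:
        return "stalemate"
    # reference cell inside the pacemaker (or left edge), mid-height
    mask = run.geometry.pacemaker_mask
    i_ref = run.geometry.ny // 2
    j_ref = int(np.flatnonzero(mask[i_ref])[0]) if mask[i_ref].any() else 0
    t, V = run.cell_trace(i_ref, j_ref)
    upstrokes = detect_cycles((t, V), threshold_mV)
    if len(upstrokes) < 2:
        return "pacemaker_only"
    idx = np.searchsorted(t, upstrokes)
    for k in range(len(idx) - 1):
        cycle_max = run.snapshots[idx[k]:idx[k + 1]].max(axis=0)
        if not np.all(cycle_max > full_drive_mV):
            return "pacemaker_only"
    return "full_drive"
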