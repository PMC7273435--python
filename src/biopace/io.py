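"""Plain-text serialisation: traces, scan tables, configs, snapshots.

All artefacts are delimited text with ``#``-prefixed header lines so
every output is self-describing and diffable.
"""

from __future__ import annotations

import io as _io
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from .tnnp06 import CellParameters, CellState, STATE_NAMES
from .single_cell import ScanResult, VoltageTrace

__all__ = [
    "write_trace", "read_trace",
    "write_scan", "read_params_config",
    "write_state", "read_state",
    "write_field", "read_field",
    "write_ecg",
]


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_trace(trace: VoltageTrace, path) -> None:
    """Voltage trace (and any recorded currents) as TSV."""
    cols = {"t_ms": trace.t, "V_mV": trace.V}
    if trace.currents:
        cols.update({f"{k}_pA_pF": v for k, v in trace.currents.items()})
    meta = {}
    if trace.params is not None:
        meta = {f.name: getattr(trace.params, f.name)
                for f in fields(trace.params)}
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)


def read_trace(path) -> VoltageTrace:
    df = pd.read_csv(path, sep="\t", comment="#")
    currents = {c[:-len("_pA_pF")]: df[c].to_numpy()
                for c in df.columns if c.endswith("_pA_pF")} or None
    return VoltageTrace(df["t_ms"].to_numpy(), df["V_mV"].to_numpy(), currents)


def write_scan(result: ScanResult, path) -> None:
    """One row per scanned value: features plus automaticity flag."""
    with open(path, "w") as fh:
        fh.write(_header_lines({"parameter": result.parameter,
                                "n_errors": len(result.errors)}))
        result.to_frame().to_csv(fh, sep="\t", index=False)


def read_params_config(path) -> CellParameters:
    """Flat ``name = value`` overrides onto the default parameters.

    Lines starting with ``#`` are comments; ``cell_type`` may be given
    by name, everything else must be a number.
    """
    overrides: dict = {}
    cell_type = None
    valid = {f.name for f in fields(CellParameters)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'name = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key == "cell_type":
            cell_type = val
        else:
            overrides[key] = float(val)
    if cell_type is not None:
        return CellParameters.for_cell_type(cell_type, **overrides)
    return CellParameters(**overrides)


def write_state(state: CellState, path) -> None:
    """Cell-state snapshot as a two-row delimited table."""
    pd.DataFrame([state.to_array()], columns=list(STATE_NAMES)).to_csv(
        path, sep="\t", index=False)


def read_state(path) -> CellState:
    df = pd.read_csv(path, sep="\t")
    return CellState(**{n: float(df[n].iloc[0]) for n in STATE_NAMES})


def write_field(field: np.ndarray, path, meta: dict | None = None) -> None:
    """A single ny x nx voltage field as TSV (one row per grid row)."""
    with open(path, "w") as fh:
        if meta:
            fh.write(_header_lines(meta))
        np.savetxt(fh, np.asarray(field), delimiter="\t", fmt="%.6g")


def read_field(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", comments="#")


def write_ecg(trace, path) -> None:
    """Two-column (t, signal) TSV."""
    meta = {}
    if getattr(trace, "electrode", None) is not None:
        meta = {"x0_mm": trace.electrode.x0, "y0_mm": trace.electrode.y0}
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        pd.DataFrame({"t_ms": trace.t, "ecg_au": trace.signal}).to_csv(
            fh, sep="\t", index=False)
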