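"""Unit and property tests of the TNNP06 ionic model."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biopace import CellParameters, CellState, compute_currents, step
from biopace.tnnp06 import CURRENT_NAMES, K_O, RESTING_STATE, RTONF


def test_defaults_match_normal_values():
    p = CellParameters()
    assert p.g_Na == pytest.approx(14.838)
    assert p.g_CaL == pytest.approx(3.98e-5)
    assert p.g_bCa == pytest.approx(5.92e-4)
    assert p.g_to == pytest.approx(0.073)
    # the pacemaker conversion 0.05 nS/pF is 0.93% of the normal g_K1
    assert 0.05 / p.g_K1 == pytest.approx(0.0093, rel=0.01)


def test_cell_type_variants():
    endo = CellParameters.for_cell_type("endocardial")
    mid = CellParameters.for_cell_type("midmyocardial")
    epi = CellParameters.for_cell_type("epicardial")
    assert endo.g_to < epi.g_to
    assert mid.g_Ks < endo.g_Ks == epi.g_Ks
    with pytest.raises(ValueError, match="cell_type"):
        CellParameters.for_cell_type("septal")


def test_negative_conductance_rejected():
    with pytest.raises(ValueError, match="g_Na"):
        CellParameters(g_Na=-1.0)


def test_ik1_zero_at_nernst_potential():
    ek = RTONF * math.log(K_O / RESTING_STATE.K_i)
    state = dataclasses.replace(RESTING_STATE, V=ek)
    cur = compute_currents(state, CellParameters())
    assert cur.I_K1 == pytest.approx(0.0, abs=1e-12)


def test_zero_conductance_zeroes_current():
    cur = compute_currents(RESTING_STATE, CellParameters(g_CaL=0.0))
    assert cur.I_CaL == 0.0


_COND_FOR_CURRENT = {
    "I_Na": "g_Na", "I_K1": "g_K1", "I_to": "g_to", "I_Kr": "g_Kr",
    "I_Ks": "g_Ks", "I_CaL": "g_CaL", "I_NaK": "p_NaK", "I_NaCa": "k_NaCa",
    "I_pK": "g_pK", "I_pCa": "g_pCa", "I_bCa": "g_bCa", "I_bNa": "g_bNa",
}


@pytest.mark.parametrize("current,conductance", sorted(_COND_FOR_CURRENT.items()))
def test_conductance_linearity(current, conductance):
    """Scaling a maximal conductance by alpha scales its current by alpha."""
    # use a depolarised state so every current is nonzero
    state = dataclasses.replace(RESTING_STATE, V=-20.0, m=0.4, h=0.3, j=0.3,
                                xr1=0.3, xr2=0.6, xs=0.2, r=0.3, s=0.6,
                                d=0.3, f=0.7, f2=0.8)
    base = CellParameters()
    alpha = 1.7
    scaled = base.replace(**{conductance: getattr(base, conductance) * alpha})
    i0 = getattr(compute_currents(state, base), current)
    i1 = getattr(compute_currents(state, scaled), current)
    assert i0 != 0.0
    assert i1 == pytest.approx(alpha * i0, rel=1e-12)


def test_i_ion_is_sum_of_components():
    cur = compute_currents(RESTING_STATE, CellParameters())
    assert cur.I_ion == pytest.approx(
        sum(getattr(cur, n) for n in CURRENT_NAMES), abs=1e-12)


def test_non_finite_state_rejected_with_field_name():
    state = dataclasses.replace(RESTING_STATE, Ca_i=float("nan"))
    with pytest.raises(ValueError, match="Ca_i"):
        compute_currents(state, CellParameters())


def test_settled_resting_cell_has_near_zero_net_current():
    """After settling, the quiescent default cell carries ~no net current."""
    from biopace import run_cell
    trace = run_cell(CellParameters(), duration=100.0, settle_ms=20_000.0)
    cur = compute_currents(trace.final_state, CellParameters())
    assert abs(cur.I_ion) < 0.01  # pA/pF


def test_step_scales_with_dt():
    """In the dt -> 0 limit the state change is proportional to dt."""
    p = CellParameters()
    s0 = RESTING_STATE
    dv1 = step(s0, p, 1e-4).V - s0.V
    dv2 = step(s0, p, 2e-4).V - s0.V
    assert dv2 == pytest.approx(2 * dv1, rel=1e-6)


def test_step_requires_positive_dt():
    with pytest.raises(ValueError):
        step(RESTING_STATE, CellParameters(), 0.0)


@settings(max_examples=50, deadline=None)
@given(
    V=st.floats(-100.0, 60.0),
    gate=st.floats(0.0, 1.0),
    ca=st.floats(1e-5, 1e-2),
)
def test_gates_stay_in_unit_interval(V, gate, ca):
    """Rush-Larsen updates keep every gate in [0, 1] at dt = 0.02 ms."""
    state = dataclasses.replace(
        RESTING_STATE, V=V, m=gate, h=1 - gate, j=gate, xr1=gate,
        xr2=1 - gate, xs=gate, r=gate, s=1 - gate, d=gate, f=1 - gate,
        f2=gate, fcass=1 - gate, Ca_ss=ca)
    out = step(state, CellParameters(), 0.02)
    for name in ("m", "h", "j", "xr1", "xr2", "xs", "r", "s",
                 "d", "f", "f2", "fcass", "R_prime"):
        assert 0.0 <= getattr(out, name) <= 1.0


def test_state_roundtrip_and_validation():
    s = RESTING_STATE
    assert CellState.from_array(s.to_array()) == s
    s.validate()
    with pytest.raises(ValueError, match="gate m"):
        dataclasses.replace(s, m=1.5).validate()


def test_trace_converges_under_step_refinement():
    """100 ms at dt = 0.02 vs dt = 0.002 ms: V traces agree within 0.5 mV."""
    from biopace import run_cell
    p = CellParameters(g_K1=0.05)
    a = run_cell(p, duration=100.0, dt=0.02, record_stride=1.0)
    b = run_cell(p, duration=100.0, dt=0.002, record_stride=1.0)
    assert np.max(np.abs(a.V - b.V)) < 0.5
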