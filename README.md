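# biopace

Simulation of a **biological pacemaker** made from human ventricular
myocytes by depressing the inward-rectifier potassium current I_K1 —
for computational cardiac electrophysiologists studying how such a
pacemaker paces, and what it takes for it to *drive* surrounding
tissue.

Ventricular cells are normally quiescent because I_K1 clamps the
membrane near its resting potential (about −86 mV).  Genuine
sinoatrial pacemaker cells lack I_K1.  `biopace` models the
conversion: each cell is a ten Tusscher–Panfilov 2006 (TNNP06) human
ventricular myocyte,

```
dV/dt = −(I_ion + I_stim)/C_m
I_ion = I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL
      + I_NaK + I_NaCa + I_pK + I_pCa + I_bCa + I_bNa
```

with I_stim = 0 throughout.  Reducing the inward-rectifier maximal
conductance g_K1 from 5.405 to 0.05 nS/pF (0.93 % of normal) unmasks
spontaneous pacing: the background currents I_bNa and I_bCa and the
Na⁺/Ca²⁺ exchanger drive the slow diastolic depolarisation, and I_CaL
(with I_Na) the upstroke.  The package provides:

- **`biopace.tnnp06`** — the full ionic model (endo/mid/epicardial
  variants, every conductance overridable), integrated with forward
  Euler + Rush–Larsen at dt = 0.02 ms;
- **`biopace.single_cell`** — pacemaker runs, conductance scans
  (g_bCa, g_Na, g_CaL, g_to), and bisection for the largest g_K1
  fraction that still supports automaticity;
- **`biopace.features`** — AP feature extraction (cycle length,
  dV/dt_max, peak potential, maximum diastolic potential);
- **`biopace.tissue`** — a 2D heterogeneous monodomain sheet
  (100 × 50 cells, endo/mid/epi columns, dx = 0.15 mm) with a
  configurable pacemaker region and diffusion map (the weak-coupling
  pacemaker: 23 columns with D at 9 % of the normal 0.154 cm²/s), and
  a stalemate / pacemaker-only / full-drive classifier;
- **`biopace.ecg`** — a pseudo-ECG at a virtual electrode 15 mm beyond
  the right tissue edge;
- **`biopace.scenarios`** — a registry that reconstructs every named
  experiment configuration (no external data), with half-size twins
  for quick runs.

## Worked example

```python
from biopace import CellParameters, extract_features, run_cell
from biopace.single_cell import STABLE_SETTLE_MS

pace = CellParameters(g_K1=0.05)           # 0.93 % of the normal g_K1
trace = run_cell(pace, duration=20_000, record_stride=0.1,
                 settle_ms=STABLE_SETTLE_MS)
f = extract_features(trace.window(10_000))
print(f"period    {f.period:7.1f} ms")
print(f"dV/dt_max {f.dvdt_max:7.2f} V/s")
print(f"peak V    {f.peak_V:7.1f} mV")
print(f"MDP       {f.mdp:7.1f} mV")
print(f"cycles    {f.n_cycles:4d}")
```

prints

```
period      853.9 ms
dV/dt_max    5.27 V/s
peak V       27.0 mV
MDP         -75.1 mV
cycles      11
```

i.e. the converted cell fires spontaneously about every 0.85 s, with a
slow (≈5 V/s) calcium-driven upstroke and a maximum diastolic
potential of −75 mV — well above the −86 mV resting potential of the
unmodified cell.  The `settle_ms` pre-integration matters: the slow
intracellular Na⁺/K⁺ balance takes minutes of simulated time to
equilibrate, and the period measured without settling is ~13 % shorter
(see `docs/methods.md`).

The same experiments are available from the shell:

```
biopace list                        # registered scenarios
biopace run fig5_gna_scan           # g_Na scan, writes a TSV table
biopace run weak_coupling_small     # half-size 2D run + drive outcome
biopace threshold                   # bisect the g_K1 automaticity boundary
```

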