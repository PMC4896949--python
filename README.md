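# magshield

Monte Carlo dose evaluation for **active superconducting magnetic shields**
against galactic cosmic rays (GCR).  Long-duration crews in interplanetary
space are exposed to fully ionized nuclei (Z = 1..28, 1..10^5 MeV/n) whose
ionization losses in tissue drive the annual dose equivalent; large
high-temperature-superconductor magnets (solenoid and toroid
configurations) have been proposed to deflect these particles before they
reach the habitat.  `magshield` transports charged nuclei through
parameterized shield/habitat geometries and region-wise magnetic field
maps, scores ionization losses in water-cylinder phantoms, and converts
them to annual dose equivalents — the quantities used to compare shield
designs by mass, field integral and dose reduction.

It is a library for health-physics and mission-design work: the importable
API plus `examples/` scripts are the main interface, with a thin
`magshield` CLI for quick runs.

## The model in brief

- **Ionization loss** (Bethe): dE/dx = K z²(Z/A)/β² [½ ln(2 m_e c²β²γ²T_max/I²) − β² − δ/2],
  Bragg additivity for compounds, Sternheimer density correction.
- **Deflection**: rigidity R = p/(Ze); small-angle estimate θ ≈ 0.29979·BL/R
  for reasoning, exact helical stepping (F = q v × B) in transport.
- **Dose equivalent**: each deposit contributes ε = Q(L)·dE/m, with L the
  unrestricted LET in water and Q(L) the piecewise quality factor
  (1 for L ≤ 10; 0.32L − 3.2 for 10 < L < 100; 300/L above).
- **Aggregation**: d_z = Σ_j [Σ_i ε_i]_j (A/N_j) f_z(E_j)ΔE_j t over an
  isotropic-flux surface source with acceptance A = πS, summed over
  Z = 1..28 into skin/BFO/body tables (cSv/y) with RMS-across-phantom
  uncertainties.
- **Source**: synthetic CREME-like spectra (power-law interstellar form,
  force-field solar modulation, built-in abundances), or user flux tables
  (CSV).

Transport is ionization-only by default; a clearly labeled toy nuclear
model exists for qualitative studies.  See `docs/methods.md` for
assumptions, parameter defaults and limitations.

## Worked example

```bash
python examples/field_integrals.py
```

prints

```
diametral chord integral : 8.00 T m (expected 8)
mean over parallel chords: closed form 6.28, Monte Carlo 6.29 T m (published 6.3)
field at habitat center  : (0.0, 0.0, 0.0) T (shield fields are confined)
```

— the 8-m, 1 T shield solenoid of the 6+1 extendable-solenoid
configuration has a maximum field integral of 8 T·m on a diametral chord;
averaged over parallel chords the geometric mean is B(π/4)D = 6.28 T·m,
and the habitat itself sits in a field-free region.

```bash
python examples/shield_masses.py
```

prints the component mass table of the continuous-coil toroid and closes
the accounting against the published figures:

```
support cylinder :  16.86 t  (published 16.8 t)
120-coil toroid  :  79.00 t  (published 79 t, calibrated)
8 Tm shield total:  95.86 t  (published 95.8 t)
```

`examples/free_space_dose.py` prints the annual skin/BFO/body dose table
in free space at solar minimum and maximum and the solar-cycle body-dose
reduction (~50% with the synthetic spectra); `examples/bl_scan.py` shows
the primary proton+He body dose falling as the toroid field integral
rises from 8 to 100 T·m; `examples/performance_metrics.py` recomputes the
published shield performance statistics (field on/off fractions, % field
contribution) from the published dose cells.

A quick CLI run:

```bash
magshield run --fixture free_space --z 1,2 --n-per-z 2000 --seed 1
magshield masses sr2s_cct --bl 8
```

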