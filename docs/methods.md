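# Methods

`magshield` evaluates the radiation-protection performance of active
superconducting magnetic shields for deep-space habitats: galactic
cosmic-ray (GCR) nuclei are transported through a parameterized
shield/habitat geometry and a region-wise magnetic field map, their
ionization losses are scored in water-cylinder phantoms, and the scores
are converted to annual dose equivalents.  This note records the model,
its assumptions, the tunable parameters, and the choices made where the
design was genuinely open.

## Single-particle physics

Projectiles are bare nuclei with charge Z = 1..28 and kinetic energy
E (MeV per nucleon).  Per-nucleon rest energy is 938.272 MeV for protons
and 931.494 MeV (one atomic mass unit) otherwise; this bookkeeping matches
the MeV/n convention throughout.  Magnetic rigidity is
R = A sqrt(E(E + 2 m_n)) / (1000 Z) GV.

The mean ionization loss is the Bethe formula

    dE/dx = K z^2 (Z/A) / beta^2 [ 1/2 ln(2 m_e c^2 beta^2 gamma^2 T_max / I^2)
                                   - beta^2 - delta/2 ]   (MeV cm^2/g)

with T_max the free-electron kinematic limit and delta the density-effect
correction.  Compounds use Bragg additivity (mass-fraction-weighted Z/A,
logarithmic-mean I); water carries an effective I = 75 eV.  delta uses
tabulated Sternheimer constants for water, aluminum, copper, graphite and
titanium, and the asymptotic plasma-energy form (clipped at zero) for
other materials; a configuration flag can force delta = 0.  Radiative
losses, nuclear stopping below ~keV, restricted LET and energy-loss
straggling are out of scope: energy is deposited continuously and locally
("unrestricted" LET), and delta electrons are not tracked.

Unrestricted LET in water is L = dE/dx(water) x rho_water x 0.1 (keV/um),
evaluated at the particle's current velocity regardless of the host
material, because the quality factor is defined on water LET.  The quality
factor defaults to the piecewise form

    Q(L) = 1 (L <= 10), 0.32 L - 3.2 (10 < L < 100), 300/L (L >= 100),

which is continuous at L = 10 and deliberately discontinuous at L = 100
(Q jumps from 28.8 to 3.0).  These constants differ from the ICRP-60
convention (0.32 L - 2.2; 300/sqrt(L)); both are implemented behind a
mode switch (`TransportSettings.q_mode`), default "printed", and whether
the printed constants are a typographical variant of ICRP-60 is left
open.  The discontinuity materially shapes the dose-equivalent depth
profile of Z >= 10 ions (see "Known limitations").

## Geometry and materials

Fixtures are ordered lists of primitives (boxes with optional yaw,
solid/annular cylinders, disks) with containment-or-disjoint nesting,
validated at construction by sampled overlap tests.  The material at a
point is that of the innermost containing component.  Masses are analytic
volume x density with nested volumes subtracted.  Coaxial fixtures (all
z-aligned cylinder shells — every transport-heavy configuration) use
compiled numba kernels for boundary search and containment; rotated-box
geometries fall back to per-shape Python methods.

The catalog covers: free space (3-m vacuum cube, one phantom); a 4-m
ESA-style habitat (1.8-cm Al); the habitat-plus-propulsion spacecraft;
the double-helix solenoid toroid (coils represented, as in the source
simulations, by 8 x 90 um copper plus a 2-mm carbon shell) at BL = 4 T m;
the MgB2 racetrack toroid (Cu/Al/Ti/MgB2 layers of 0.30/1.65/1.50/1.55 cm
plus a 5-mm Al frame) at 4.9 T m; the 6+1 extendable solenoid shield (six
8-m, 20-m solenoids as 111-um Cu cylinders with graphite cores and
spokes, a 6.4-m compensation coil, 6-m habitat, 30-m generation cube);
and the SR2S continuous-coil toroid (Columbus-style 4.5-m habitat, Al-B4C
support cylinder, smeared MgB2 cable-core coil pack) with a field-integral
scan over {8, 11.5, 23, 50, 100} T m.

Open geometry details were resolved as follows and are visible in the
mass report rather than hidden:

- The Al-B4C support cylinder interprets 5.5 m as the *outer* diameter;
  the analytic mass (16.86 t) then reproduces the published 16.8 t within
  0.5%.
- The SR2S coil cross-sections are not dimensioned in the configuration
  description; the smeared cable-core thickness is calibrated
  analytically so the 120-coil toroid mass equals the published 79 t
  (120.1 t for the enlarged 11.5/23 T m coils).  Field and material maps
  then stay mutually consistent.
- The Columbus habitat shell computed from its printed dimensions weighs
  ~6 t against the published 4.36 t; the residual reflects unprinted
  interior detail and is reported, not fudged (per-fixture calibration
  factor, default 1.0).
- The ESA spacecraft (habitat 5.5 m + propulsion 6 m) exceeds the 10-m
  generation box, so the propulsion cylinder is clipped at the box face —
  its effective thickness is set by the spacecraft's position in the box.
- Six-phantom placement: cylinders 1 and 6 on the habitat axis at
  +-(L/2 - 1 m); cylinders 2-5 at 90-degree azimuths with the outer
  phantom surface 10 cm from the inner wall, centered longitudinally.
- NIAC shield solenoids sit on a ring of radius 8 m (tangent 8-m coils);
  the published ring radius is not printed.

## Magnetic fields

Fields are superpositions of bounded regions: uniform axial fields in
cylinders (solenoids) and azimuthal fields in annuli (toroids).  The
toroidal profile defaults to uniform magnitude B0 = BL / (radial width),
with a 1/r profile normalized to the same radial chord integral as an
option.  Fields are exactly zero outside their regions — no fringe or
return flux — matching the confined-field idealization of the source
studies.  The compensation-coil field defaults to 0 T because confined
shield fields make habitat nulling a no-op in this idealization; a
nonzero value is configurable.  Line integrals of |B_perp| are computed
by segmenting rays at region boundaries and applying 16-point
Gauss-Legendre quadrature per segment (exact for uniform regions).

## GCR source

The synthetic spectrum emulates CREME-2009-style per-charge differential
fluxes on a 48-bin logarithmic grid over 1..1e5 MeV/n.  The local
interstellar spectrum is a power law in total energy per nucleon with
index 2.7 (the canonical high-energy GCR index) and built-in relative
abundances for Z = 1..28 representative of measured composition near
1 GeV/n; fluorine carries no anomalous-component enhancement, which
reproduces the local structure in the solar max/min flux-ratio sequence.
Solar modulation uses the one-parameter force-field transform with
phi = 500 MV (solar minimum) and 1100 MV (solar maximum).  The absolute
normalization sets the modulated solar-minimum proton flux at 1 GeV to
2.0e-4 cm^-2 sr^-1 s^-1 MeV^-1, a representative measured value.  These
spectra have realistic shapes and epoch ratios but are synthetic: absolute
dose magnitudes inherit their normalization and are approximate by
design, which is why published dose magnitudes are compared only through
derived ratios, masses and closed-form physics.

Primaries are generated on the faces of the generation box as an
isotropic-flux surface source: uniform position on the active faces
(barrel = 4 lateral, endcaps = 2 axial, full = all 6) and cosine-law
direction about the inward normal.  This is the unique surface sampling
reproducing an isotropic interior flux, and its acceptance is
A = pi x (active area); a 3-m cube with all sides active gives
1.696e6 cm^2 sr.  Energies are drawn either per bin (fixed bin-center
energy, aggregation divides by the per-bin count) or from the flux by
inverse CDF (log-uniform within a bin).

## Transport

Propagation alternates exact helical advancement in the local field (the
direction vector is rotated about B; the parallel velocity component,
|v|, and the energy are conserved identically) with continuous
slowing-down in matter, dE = dE/dx x rho x ds deposited along the step.
Step length is the minimum of: 2% fractional energy loss, 0.05 rad of
bending, the distance to the next geometry or field-region boundary, and
a 10-m cap.  Particles stop below 1 MeV/n (residual energy deposited
locally) or at the generation-box boundary.  Deposits inside a phantom
are attributed to skin/BFO/body by sub-sampling the step chord at 0.5-mm
resolution, which keeps the 2-mm shell doses unbiased without shrinking
the physics step.  Transport of primaries consumes no random numbers, so
a fixed seed yields identical primary samples across configurations —
runs at different field integrals are exactly common-random-number
paired, which stabilizes trend comparisons at desk-scale statistics.

A toy nuclear model (off by default, and off in every quantitative
result) exists for qualitative secondary build-up exploration: inelastic
interaction lengths from the Bradt-Peters geometric cross-section
sigma = pi r0^2 (A_p^(1/3) + A_t^(1/3) - b)^2 with r0 = 1.26 fm, b = 1;
on interaction, a projectile fragment continues at the projectile
velocity and evaporation-like nucleons (exponential, 20 MeV mean) are
emitted isotropically.  It makes no claim of Geant-class hadronic
fidelity, and published secondary-dose magnitudes cannot be validated
with it.

## Dosimetry

The phantom is a 24-cm-diameter, 180-cm-long water cylinder (81.4 kg).
Skin is the outer 2 mm (lateral shell and end disks, 2.87 kg); BFO is a
2-mm radial shell at 5-cm depth excluding the axial ends (1.47 kg,
radial-only per the pictured layout); body is the full volume.  Each
deposit contributes eps = Q(L) dE/m per region.  Annual doses follow

    d_z = sum_j [sum_i eps_i]_j (A / N_j) f_z(E_j) dE_j t      (per-bin)

summed over bins and charges, with the spectrum-sampled alternative
d_z = (sum eps) A (integral flux / N_z) t; both estimator readings are
implemented and agree within Monte Carlo scatter (tested), default
per-bin.  The exposure time defaults to one year (3.156e7 s).  Tables
are per charge group {1, 2, 3-10, 11-20, 21-28} x {skin, BFO, body} in
cSv/y (absorbed variant with Q = 1 in cGy/y), with the cell uncertainty
defined as the RMS deviation of the per-phantom means across the six
cylinders — a population-style spread that reflects both dose
nonuniformity and counting statistics, matching the source convention.

Performance statistics are ratios of table cells: on/off fraction,
percent field contribution 100 (off - on)/off, and reference ratios, all
with quadrature error propagation.  The percent-habitat column is
reported as 100 (habitat - shield_on)/habitat and the formula is always
printed with it, because the published column is not consistently
derivable from printed cells.

## Problem sizes

Defaults are desk-scale: 1e3-1e5 primaries per charge instead of the
1e7-1e8 of the source studies, with uncertainty columns keeping the
statistics honest and seeds recorded in every manifest.  The acceptance
script uses ~1.5e3 primaries per charge for free-space epoch comparisons
and 3e4 proton+He primaries per field-integral point (on a 12-m
generation box, which raises the phantom-hit fraction without touching
the shield geometry) for the field-scan trend.  At these sizes the
monotone fall of the dose with field integral is clear in aggregate (the
100 T m dose is ~0.3 of the 8 T m dose) while individual adjacent pairs
at the stiff end of the scan can wobble within their paired
uncertainty; the reported monotone fraction states exactly what was
observed.

## Known limitations

- Ionization-only transport: no nuclear fragmentation or secondary
  production in the quantitative pipeline.  Consequently the published
  skin-vs-depth patterns that are partly driven by nuclear attenuation of
  heavy ions (e.g. skin >> BFO for Z >= 3 in free space) appear only
  weakly: at desk-scale statistics our absorbed-dose tables show
  skin > BFO for heavy groups, but the dose-equivalent ordering of the
  3-10 group can invert legitimately because Q(L) rises with depth for
  ions approaching L = 100 from below.  Property tests therefore pin the
  deterministic version of the pattern (short-range ions deposit in skin
  and not in BFO) rather than the spectrum-averaged ordering.
- Gammas are neither produced nor tracked; neutron transport exists only
  inside the toy model.
- Synthetic spectra: absolute doses are normalization-dependent; the
  solar-maximum body-dose reduction lands near 50% against the published
  ~40%, consistent with the power-law LIS approximation.
- The force-field epoch ratio at 1e5 MeV/n retains a ~2.7% residual for
  protons (closed-form consequence of the 2.7 index), slightly above the
  nominal "vanishes at high energy" expectation.
- The small-angle deflection formula theta = 0.29979 BL/R is an estimate
  used for reasoning and tests; transport integrates the Lorentz force
  exactly.
- Mass accounting matches published simulation masses only where the
  text fully specifies components; residuals (Columbus habitat) are
  reported per component.
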