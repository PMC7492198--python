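# Methods

This note documents the model behind `innerear`: its assumptions, the
parameters that matter, the numerical choices, and what the synthetic
excitation spectra do and do not represent.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The acoustic network

The inner ear is a linear, passive, frequency-domain acoustic circuit.
Pressures are in Pa, volume velocities in m³ s⁻¹, impedances in Pa·s·m⁻³;
lumped elements evaluate as Z(ω) = jω·M + R + K/(jω).  The canonical
topology (one branch per anatomical impedance) is:

```
ambient --[Z_ME]-- OW
OW --[Z_V/2]-- A --[Z_V/2]-- V        vestibule toward the third windows
V --[Z_SSC]-- CSF                     dehiscent canal (absent when intact)
V --[Z_VA]-- CSF                      vestibular aqueduct
ambient --[P_IC]-- CSF                CSF reservoir (ideal pressure branch)
OW --[Z_SV]-- SV_BASE                 scala-vestibuli entrance
SV_BASE --[Z_C]-- ST_BASE             basilar membrane (U_C measured here)
SV_BASE --[Z_SVD/2]-- SV_PORT --[Z_SVD/2]-- SV_APEX
SV_APEX --[Z_H]-- ST_APEX             helicotrema
ST_APEX --[Z_STD/2]-- ST_PORT --[Z_STD/2]-- ST_BASE
ST_BASE --[Z_CA]-- CSF                cochlear aqueduct
ST_BASE --[Z_RW]-- ambient            round window
```

Two structural choices deserve emphasis, both forced by the behavior the
model must reproduce:

* **The basilar-membrane branch sits at the base**, with the scala-duct
  ladder (Z_SVD – Z_H – Z_STD) as the parallel helicotrema path.  The duct
  ladder's mass reactance exceeds |Z_C| over most of the band, which is why
  third-window shunts at the vestibule stop mattering once their own mass
  reactance exceeds the cochlear input impedance — the dehiscence effect on
  AC hearing is intrinsically low-frequency.
* **The vestibule is a side branch.**  The scala vestibuli taps the
  oval-window node directly; the vestibule (Z_V, split into two halves with
  reporting position A at its midpoint) leads away from the cochlea to the
  canal and aqueduct openings.  This keeps the AC prediction finite even in
  the theoretical bound where the canal branch is an ideal short to the CSF
  node, and it makes the dehiscence a *return path* for bone-conduction
  fluid inertia rather than a leak in the AC line.

The solver is plain modified nodal analysis: impedance branches are stamped
as admittances (series pressure sources become Norton injections), ideal
pressure branches (the CSF reservoir; the zero-impedance canal bound) add
one current unknown each, and the ≤ 12-unknown dense complex system is
solved directly at each of 120 log-spaced frequencies between 100 Hz and
10 kHz (100, 125, 250, 300, 500 and 1000 Hz are snapped exactly onto the
grid).  Direct solution makes superposition across contributors exact to
machine precision, which the tests assert.  Infinite impedances are an
explicit `blocked` flag and are dropped from the matrix, never represented
by large floats; ideal shorts are pressure-kind branches, never tiny
impedances.

## Element values

The named lumped coefficients live in `data/model.yaml` and follow the
reference lumped-element description of this ear; ducts built from geometry
use ρ = 1000 kg m⁻³ and η = 1.0 mPa·s (perilymph/CSF as water).  Straight
tubes contribute M = ρL/A and Poiseuille R = 8ηL/(πr⁴); tapered ducts and
horns are integrated in 0.1 mm steps at the average cross-section area;
elliptic sections use the exact area for mass and the equivalent circular
radius r_eq = √(A/π) for friction (no elliptic friction correction —
resistance is sub-dominant for every element this applies to).

Three reconstructions were necessary where the reference values are
incomplete or internally inconsistent:

* **Vestibular-aqueduct horn taper.**  The aqueduct is a 2.3 mm tube of
  0.3 mm diameter followed by a 5.7 mm horn whose entry matches the tube
  area and whose end opening is an ellipse of radii 3.25 × 0.27 mm.  The
  taper law between the two ends is not stated; the package uses an
  exponential area profile, the canonical acoustic horn.  This reproduces
  the reference lumped mass 5.68e7 kg m⁻⁴ within ~5%; the resulting
  resistance coefficient is ~1.55e10 vs the reference 1.27e10 (+22%),
  which is immaterial on the analysis grid where the element is
  mass-dominated (|Z_VA| agrees within a few % at every grid frequency)
  but is a known deviation of the constructed coefficient.
* **Canal-branch impedance.**  The transcribed canal-impedance formula is typographically
  corrupted, so Z_SSC is built from the described geometry: two 6 mm canal
  limbs (cross-section tapering 2 → 1 mm²) in parallel, terminated by the
  dehiscence — a 1 mm tube of elliptic cross-section with 2:1 aspect and
  area A_D, whose plug mass ρL/A_D and Poiseuille resistance π·8e-6/A_D²
  are included.  Each limb is shortened by the hole's semi-major axis
  a = 2·√(A_D/2π).  The unambiguous reference terms (duct mass constant
  2.83e6, duct resistance 3.9e7, hole resistance π·8e-6/A_D²) serve as
  cross-checks, not inputs.
* **Middle-ear damping.**  The transcribed frequency-independent middle term
  of Z_ME is adopted as a resistance of 1.2e10 Pa·s·m⁻³, reading the
  transcribed exponent as corrupted.  Three considerations fix this: the
  annular-ligament stiffness 8.1e13/(jω) must dominate Z_ME at low
  frequency for oval-window reinforcement to throttle the stapes flow
  (otherwise a 100× stiffening costs ~20 dB rather than the ~tens of dB
  the reinforcement predictions show, and a 10× OW stiffening could never
  resemble a 100× RW stiffening); the window-return inertia path through
  Z_ME must be available at mid frequencies for the BC improvement under a
  dehiscence to peak near 300 Hz and decay above it; and 1.2e10 gives the
  2 kHz middle-ear resonance a quality factor of ~1.6, a physically
  reasonable damping.

## Bone-conduction excitation

The skull carries a longitudinal one-dimensional wave: every bony point
shares one acceleration amplitude *a* (default 1 m s⁻², arbitrary — all
outputs are ratios) and the phase exp(−jω·s/c) of its position projected
on the propagation direction.  Default speed c = 300 m s⁻¹ (configurable
100–1000; the low-frequency predictions are insensitive to it), direction
along the model axis.  Attenuation is neglected over the ~10 mm model span.

The in-plane layout is schematic: the coiled scalae (2.5 turns, outer
radius 5 → 1.6 mm linear in winding angle) lie with their base on the +x
axis; each scala's sections sit on its own *centerline* spiral (outer
radius minus half the local duct width), which is the path whose ρ·Δl/A
masses also integrate to within ~10% of the lumped duct rows.  The round
window sits at the scala-tympani base; the oval window is offset 3.0 mm
further along the axis; the 5.8 mm vestibule continues from the oval
window away from the cochlea to the canal/aqueduct openings.  The
oval-to-round-window axial separation is not an anatomical datum given to
the model; 3.0 mm is anatomically plausible and was fixed, once, so that
the crossover between the two fluid-inertia return paths (below) sits near
300 Hz, where the BC improvement under a dehiscence is reported to peak.

**Fluid inertia.**  Each fluid branch carries a series pressure source
equal to the line integral ρ·a·∫φ(s)·ds of the phased inertial body force
over the branch's axial extent.  Because this assignment is a conservative
field, rigid-body motion (c → ∞) produces zero net source around every
closed fluid loop, and the drive available to the windows equals ρ·a times
the oval-to-round-window separation — the correct rigid-body physics, and
a property test.  The consequence for pathology: the fluid-inertia flow
has two return paths, through the vestibular aqueduct (or dehiscence) and
through the middle ear, and their relative impedance sets both the +10 dB
round-window-limited improvement floor at 100 Hz and the mid-frequency
peak of the dehiscence effect.  The module also exposes the conventional
lumped sources P_V, P_SV, P_ST (ρ·L_eff·a with the component-centroid
phase) for inspection.

**Compression.**  Each of the 180 five-degree sections of each scala emits
ΔU = −jω·A·(ξ_far − ξ_near), the rate of section-volume change under the
wall-displacement difference at its two boundaries, with the fluid
incompressible.  Per-section sources are condensed onto the mid-duct port
of each scala by a current divider over cumulative duct mass plus the
terminating loads (computed numerically from the assembled netlist, duct
excluded); half of each section's own mass is assigned to either side, and
the basal shares sum to the port source.  The vestibule contributes a
single-segment source of the same kind, injected at the vestibule node.
Note the spectral normalization: at constant *acceleration* the
compression sources are nearly flat in frequency; the familiar statement
that they shrink toward low frequency holds per unit *displacement*
(∝ ω²), and the property test is phrased accordingly.  All reported
quantities are fixed-frequency ratios, so the normalization cancels.

**Stapes-path drives and CSF pressure.**  The middle-ear transfer
function, the ossicle-inertia stapes velocity, the ear-canal BC pressure
and the intracranial pressure are not derivable from the model's geometry;
they enter as smooth log-log piecewise-linear stand-in spectra
(`data/sources.yaml`) with documented breakpoints — explicitly *not*
digitized measurement data.  Their absolute scales are arbitrary; every
reported output either cancels them exactly (per-contributor changes, AC
changes) or is evaluated where one contributor dominates the power sum by
≥ 10 dB, which the acceptance script verifies at run time.  All three
stapes-path drives are applied as a Thévenin pressure source in series
with Z_ME, calibrated so the stand-in curve equals the stapes volume
velocity under the healthy load; under pathology the network re-loads the
source, so stiffening the oval window feeds back on stapes flow — the only
convention consistent with the reinforcement predictions.  The CSF
pressure is one shared source at the CSF node (the aqueduct and dehiscence
openings are physically close); its stand-in is flagged unusable below
250 Hz for absolute plots, while change quantities remain defined.

**Calibration.**  The stand-in contributors are pinned to the
(scale-free) fluid-inertia contributor in the healthy ear: ossicle inertia
2 dB below it at its own resonance peak, compression 10 dB below at
500 Hz, ear-canal 15 dB below at 500 Hz, CSF 10 dB below at 250 Hz (its
lowest valid frequency — the pathway rolls off steeply with frequency, so
a high-frequency anchor would let it overtake fluid inertia at the bottom
of the grid).  These offsets encode the qualitative healthy-ear ordering
(fluid inertia dominant overall; ossicle inertia prominent at 1–2 kHz)
and are the conditions under which all totals are computed; they are
recorded in every run's metadata.  An infeasible calibration request
(zero flow at the anchor) raises, never clips silently.

## Numerical choices

* Dense complex LU per frequency; no iterative methods — exactness and
  determinism over speed (the full acceptance run takes seconds).
* Half-elliptic scala areas: A = (π/2)·(width/2)·height, literal reading
  of the stated width/height pairs.
* Horn/taper discretization: 0.1 mm steps, endpoint-average area per step;
  halving the step moves the aqueduct coefficients by < 1%.
* Doubling the scala discretization to 360 sections moves the lumped
  compression sources by < 0.5 dB at every grid frequency (tested).
* Degenerate inputs are rejected with diagnostics: non-positive
  frequencies, radii or wave speeds; empty combinations; sources on
  blocked branches; disconnected networks; zero reference power in a dB
  change.

## What the synthetic sources do and do not show

The stand-in spectra make the *relative-change* predictions meaningful —
those cancel the spectra entirely or are single-contributor-dominated —
but absolute BM-flow levels, and any comparison of absolute intra-cochlear
pressures against measurement, are outside what this package can support:
no reference source magnitudes exist to calibrate against, and the model is
one-dimensional while real skull vibration is three-dimensional (power
summation over contributors, rather than coherent phase summation, is
used for exactly that reason).  Passing tests therefore certify the
network mechanics and the change predictions, not absolute sensitivity.

## Known limitations

* The reference model's network wiring is reconstructed from its textual
  description; the reconstruction reproduces the qualitative mechanism set
  (low-frequency AC loss from cochlear-impedance reduction, RW-limited BC
  improvement floor, aqueduct-controlled CSF pathway, OW-reinforcement
  futility under a dehiscence) and most reference numbers within a few dB,
  but the healthy-ear fluid-inertia reference around 250–450 Hz — where
  the aqueduct-return and window-return loops are in anti-phase — comes
  out a few dB weaker than in the reference model, so the dehiscence
  change/ABG maxima run ~4–7 dB high and decay toward high frequency more
  slowly (the AC change is back under 3 dB just above 1 kHz, the
  fluid-inertia change only above ~2.5 kHz).
* After a 100× round-window stiffening the only scala-tympani exits are
  the stiffened window and the 10 mm × 0.15 mm cochlear aqueduct; their
  parallel impedance bounds the low-frequency BC loss near −21 dB at
  100 Hz, deeper than the −17 dB the reference model reports.
* Dehiscence position along the canal is fixed at the midpoint; canal
  geometry beyond the two tapering limbs, radiation end-corrections at
  the hole, thermoviscous corrections, middle-ear cavity acoustics and
  sound-induced vestibular responses are all out of scope.
* Reporting positions A–D are schematic; with AC drive the model keeps A
  and B within 0.02 dB and places C ~3 dB below B above 1 kHz, while with
  inertial BC drive B sits several dB below A — position-level validation
  against cadaver pressure measurements is not attempted here.
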