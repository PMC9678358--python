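# Methods

This note documents the models, numerical choices and calibrations behind
`nocimech`, and what the synthetic-data generators do and do not emulate.
Internal units are μm / mN / MPa throughout (1 MPa·μm² = 1 μN).

## Contact model

The probe–tissue contact is the classical sphere-on-surface (Hertz)
solution for a rigid sphere on an elastic half-space. Probe "sizes"
(30/60/100/200 μm) are tip diameters; formulas use the radius. The model
is valid for indentation depth d < r; deeper pokes puncture the cuticle
experimentally, so the restriction is physical as well as mathematical.
The effective modulus uses the rigid-indenter form E* = E/(1 − ν²).

Device conversions: d = D − B (piezo step minus beam deflection, both
measured optically); the strain gauge is calibrated gravimetrically with
water steps (1 g/mL, g = 9.8 m/s², so 100 μL ≙ 0.98 mN — the constants
are fixed to reproduce that printed step) and fitted as an ordinary
least-squares line with a free intercept, since a forced zero intercept is
not stated anywhere for the calibration curve.

## Layered indentation solver

The stress field under the probe is computed for the experimental
composite: cuticle (10 μm thick, ν = 0.45) tightly bonded to a PDMS pad
(1000 μm, 2.6 MPa, ν = 0.45) with a fixed bottom. The much softer muscle
layer (~10 kPa) contributes negligibly to the force balance and is
omitted. Both materials are linearly elastic and the kinematics are
small-strain, even though d = 20 μm exceeds the cuticle thickness — this
mirrors the linearly-elastic treatment the pipeline is built to
reproduce, and its output should be read as the linearized stress
pattern, not a finite-strain prediction.

The solver is an axisymmetric displacement-based FEM:

- **Mesh** — tensor-product grid of bilinear quadrilaterals, radially
  uniform at 0.25 μm under and around the contact (to 50 μm), 0.5 μm to
  150 μm, then geometrically coarsened to a 1500 μm outer radius; 16
  geometrically graded element rows through the cuticle, coarsening into
  the substrate. The far radial extent matters: truncating at ~300 μm
  with a free wall loses ~6% of the contact force under displacement
  control.
- **Integration** — full 2×2 Gauss. At ν = 0.45 on this mesh, volumetric
  locking is negligible (verified against the Hertz oracle below);
  under-integrating the volumetric term instead admits spurious
  checkerboard pressure modes that corrupt the contact reactions.
- **Contact** — rigid frictionless indenter under displacement control,
  enforced node-wise by an active-set iteration: nodes whose reaction
  turns tensile are released, surface nodes penetrating the indenter are
  added, until the set is complementarity-consistent (typically 3–6
  sweeps). Node numbering keeps the stiffness bandwidth proportional to
  the axial node count, so each sweep is a cheap banded sparse LU.
- **Indenter profile** — the exact sphere by default. At the experimental
  d/r = 20/30 the osculating parabola ρ²/(2r) is a poor shape
  approximation and widens the contact patch; the parabola remains
  available (`indenter="parabolic"`) because its homogeneous half-space
  solution *is* the closed-form Hertz solution (a = √(rd) exactly), which
  makes it the right profile for oracle validation.
- **Outputs** — P_P is the contact pressure recovered from the nodal
  reactions divided by consistent lumped ring weights; T_L is the maximum
  tensile in-plane principal stress at the top surface, clipped at zero.
  Surface stresses are recovered traction-consistently: in-plane strains
  from the surface radial displacement (ε_rr = du_r/dρ, ε_θθ = u_r/ρ) and
  the out-of-plane strain eliminated via the known surface traction
  σ_zz = −p, which keeps T_L clean across the contact edge where
  element-interior strain recovery is noisy.

**Validation.** In the homogeneous limit (single material, parabolic
indenter, 60 μm probe, d = 20 μm) the solver reproduces the Hertz
pressure within 2.4% of P0 in L∞ over ρ ≤ 0.9a, the total force within
3.6% (the residual is the real finite-depth stiffening of the 1010 μm
fixed-bottom stack relative to a half-space), and the tensile peak within
0.64 μm of the contact edge. Peak locations are quoted at the 1 μm
resolution of the field maps consumed downstream; locating the maximum of
a smeared stress kink much below the grid scale is not meaningful for any
displacement-based recovery.

**Cuticle modulus.** The literature range is 1–10 MPa with the displayed
value unstated. Solving across the range shows the lateral-tension peak
sits at 22–25 μm (just outside the contact edge) for E_cuticle ≲ 2.6 MPa
and migrates to 26–34 μm for stiffer films, while the long ρ⁻²-like
tension tail — the carrier of the expanded receptive field — persists for
E_cuticle ≥ 2.6 MPa. The default is therefore E_cuticle = 2.6 MPa (equal
to the pad), the value in the printed range that reproduces both the
reported 20–25 μm peak position and the tail; it is a config parameter.

## Morphometrics

Arbors are planar rooted trees (da dendrites tile the 2D epidermal
sheet); 3D SWC input is accepted with z dropped and a warning. The
*modified Sholl density* is the number of circle crossings divided by the
circle circumference (μm⁻¹) — for a mostly radial planar arbor this is
also the local dendritic length per unit area. Crossings are counted as
quadratic roots of the segment–circle intersection on the half-open
parameter interval [0, 1), so shared endpoints count once and tangencies
count once. Ring spacing defaults to 10 μm.

Distance maps are exact point-to-segment minima (`method="exact"`, the
in-package oracle) or a KD-tree query against points sampled along the
segments at half-pixel spacing (`method="kdtree"`, default; error well
under half a pixel). The dendritic territory is a disc of radius 220 μm
about the soma — just beyond the 200 μm distal stimulus circle.

Stimulus sampling: proximal/distal modes return points *on the dendrite*
within 5 μm of the 100/200 μm circles; `d_off` rejection-samples
territory points whose nearest-dendrite distance is within ±2 μm of a
target (and raises if the arbor is too space-filling for that distance to
exist, as is the case for wild-type arbors beyond ~10 μm); `uniform`
draws area-uniform points on the territory disc.

## Activation model

A placement x overlays the probe-centred field maps on the arbor.
Segments are discretized at 1 μm and sampled at sub-segment midpoints; a
sub-segment is excited when its local field value reaches 10% of that
channel's global peak (a relative threshold — the model asks about the
*shape* of the field, not absolute gating thresholds). The cell activates
when the excited length reaches the coverage threshold C_d, explored at
20/200/400 μm = 0.1/1/2% of the mean total dendritic length (each rounded
to one significant figure). Scenarios: pressure-only, tension-only, and
both (union — a sub-segment excited by either channel counts once, so the
union probability dominates each single channel by construction).

Placements are uniform over the territory disc (the study says "random
positions" without a law); probabilities are computed per cell as the
fraction of activating placements, then aggregated as mean ± std across
cells, matching the 5-cells × 100-positions design. Fields are not
re-oriented or clipped at the territory boundary; they are radially
symmetric, so orientation is moot, and the overlap outside the territory
contributes nothing because there is no dendrite there.

## Force–response model

ΔF/F0 = (F − F0)/F0 with F0 the mean fluorescence over the pre-stimulus
baseline window. The force–response relation is fitted with a
three-parameter Boltzmann, R(f) = A/(1 + exp((f0 − f)/w)) — zero lower
asymptote, since responses start near zero at zero force. The fit targets
the per-force mean across cells (the curves are displayed as mean ± sem);
per-cell fitting is available. Initialization: A = max response, f0 from
linear interpolation at half-max, w = force span / 4; Levenberg–Marquardt
via `scipy.optimize.curve_fit` with positivity bounds on A and w.
Derived: f50 = f0, f90 = f0 + w·ln 9, and generally
f(q) = f0 + w·ln(q/(1 − q)). Whether a four-parameter fit was used
originally is unstated; the three-parameter form is identifiable on
12-cell data and fixes f50 at the plateau midpoint.

## Synthetic data

**Arbors.** The generator emulates the *statistics* of imaged c4da
arbors, not their development. Tips grow radially in 2 μm shells; after
each shell the live-tip count is matched to a target crossing count
N(ρ) = 2πρ·D(ρ) by bifurcating the tips with the widest angular gaps
(space filling) or retiring the most crowded ones; headings meander
(arc-length sd 0.6 μm/shell) with mean-reversion toward the local gap
bisector (self-avoidance). The wild-type density is uniform with
D0 = L/(πR²) ≈ 0.129 μm⁻¹ set by the measured mean total length
(19,560 μm) and the 220 μm territory; an auto-calibration loop absorbs
the few-percent structural overhead of branch chords and meander.
The cut-knockdown variant keeps the wild-type proximal density and decays
exponentially (35 μm scale) beyond 100 μm; the class-III variant is
sparse throughout. Realized wild-type arbors hit the length target within
~0.5%, keep Sholl density within ±30% of its mean over 20–180 μm, and
cover ≥95% of the territory within 20 μm of a dendrite.

What the generator does *not* emulate: actual branch-order statistics,
terminal-branch dynamics, the anisotropy of real segments, inter-cell
tiling boundaries, or imaging noise. Tests passing on these arbors
validate the pipeline's computations and their calibration targets, not
any claim about real morphogenesis.

**Force–response curves.** Per cell, Boltzmann values on the preset's
force grid plus additive Gaussian noise (sd = 0.1·plateau), truncated at
zero — a pragmatic noise model; the measurement noise law is not stated.
Wild-type presets carry the measured f50/f90 (60 μm probe: 3/4 mN on a
0–5 mN grid; 30 μm probe: 0.7/1.5 mN, plateau 1.5× larger reflecting the
stronger small-probe responses, on a 0–2 mN grid). Mutant-like presets
(piezo-like, ppk26-like, double) are qualitative fixtures only — their
amplitudes are free modeling choices, not measured values.

All generators are pure functions of (parameters, seed).

## Problem sizes and determinism

The default FEM mesh has ~430 surface nodes and ~33k degrees of freedom;
one layered solve takes a few seconds on one CPU. The full activation
sweep (5 arbors × 100 placements × 3 scenarios, shared field sampling)
runs in under a minute. Every stochastic component takes an explicit seed
and the acceptance script derives all of its sub-seeds from one `--seed`.

## Known limitations

- Linear kinematics at d/t_cuticle = 2 — stress magnitudes inside the
  cuticle should be read comparatively, not as finite-strain predictions.
- No adhesion, friction, viscoelasticity, plasticity or cuticle rupture;
  no hemolymph pressure (the preparation sits on a pad, not on liquid).
- T_L is evaluated at the top surface; where the physiologically relevant
  depth lies within the cuticle is an open question of the original
  analysis and is not resolved here.
- The activation model is geometric: no channel gating kinetics, calcium
  dynamics or dendritic integration beyond the excited-length threshold.
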