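# Methods

## The question the package answers

Dry finishing and polishing of a composite restoration heats the composite
surface to roughly 140 °C. The dental pulp suffers irreversible damage once
it warms by about 5.5 °C over the 37 °C body baseline, i.e. at 42.5 °C
(the Zach–Cohen threshold). How long can a clinician polish a class II
restoration dry before the pulp reaches that threshold, and how does the
answer depend on the cavity design — and hence on the volume and placement
of the composite filling?

`pulptherm` answers this with a transient heat-conduction simulation on a
synthetic labelled voxel phantom of a molar crown, followed by a
threshold-crossing analysis of the simulated pulp temperature trace.

## Governing model

Heat conduction only:

    ρ c ∂T/∂t = ∇·(k ∇T)

with per-tissue constant properties (enamel, dentin, pulp, Filtek Supreme
XT composite). Boundary conditions:

* **Source (Dirichlet)** on the exterior composite surface: the
  finishing-tool contact temperature ramps linearly 37 → 140 °C over 5 s,
  then holds at 140 °C for 10 s (15 s total). Frictional heat generation at
  the polisher–composite contact is not modelled; the measured surface
  temperature history stands in for it.
* **Convection (Robin)** on exterior enamel faces of the anatomic crown
  above the cervical plane: `q = h (T − T_amb)` with h = 3 W/(m²·K) and
  T_amb = 37 °C, the accepted magnitude of intraoral convection. Exterior
  faces below the cervical plane (the crown base — the phantom carries no
  root) are insulated.
* **Initial condition**: uniformly 37 °C.

Not modelled, deliberately: pulpal blood flow, dentinal-tubule anisotropy
of dentin conductivity, light-curing exothermy, coolant spray, radiation,
temperature-dependent properties, and any thermo-mechanical coupling
(Young's modulus and Poisson's ratio are stored in the material records for
completeness but never used).

## Material properties

The default library (`src/pulptherm/data/materials.yaml`):

| material          | ρ (kg/m³) | k (W/m·K) | c (J/kg·K) |
|-------------------|-----------|-----------|------------|
| Enamel            | 2800      | 0.84      | 750        |
| Dentin            | 2000      | 0.36      | 1302       |
| Pulp              | 1000      | 0.0418    | 4200       |
| Filtek Supreme XT | 1500      | 1.18      | 1370       |

Source tables of this property set print densities like "2.800" under
kg/m³ and specific heats like "1.302" under J/(g·K); taken literally those
magnitudes are physically absurd (enamel lighter than air). The package
reads the periods as thousands separators — the values above, which all
match standard literature magnitudes (pulp is water-like; dentin is the
insulator relative to enamel: α_enamel > α_dentin > α_pulp). The literal
reading stays selectable (`default_library(units_interpretation="literal")`)
purely for audit.

## Phantom generator

No scanned tooth geometry is available, so the phantom is parametric:

* **Crown**: a superellipsoid (exponent 3; exponent 2 would be an
  ellipsoid, larger values more box-like) of extent 10 × 11 × 8 mm
  (mesiodistal × buccolingual × occlusogingival), sampled on a regular
  voxel grid (default 0.25 mm) with a one-voxel background margin. The
  distal aspect faces +x.
* **Enamel shell**: the region between the crown surface and the same
  superellipsoid with every semi-axis reduced by the enamel thickness
  (1 mm). This inward offset is exact on the axes and slightly thicker on
  diagonals — acceptable for a phantom.
* **Pulp chamber**: a true ellipsoid (semi-axes 2.0 × 2.5 × 1.8 mm,
  center 0.8 mm gingival of the crown center). Construction is validated:
  every pulp voxel's 26-neighbourhood must contain only pulp or dentin.
* **Cervical plane** at 25 % of crown height separates convective crown
  surface from the insulated base.
* An optional seeded uniform jitter on the implicit-surface threshold adds
  deterministic surface roughness; it is off by default.

What the generator does *not* emulate: cusps, fissures, multi-rooted
anatomy, pulp horns, the periodontal environment, or any patient-specific
geometry. Passing tests therefore demonstrate correct physics and
bookkeeping on an idealised crown, not clinical accuracy for a real tooth;
absolute crossing times shift with geometry, while the qualitative
volume/depth ordering across designs is robust.

## Cavity designs and volume calibration

Four class II designs are carved from the distal aspect (a carve region
intersected with enamel∪dentin and relabelled composite):

| design          | shape                                                | floor_x (mm) | dentin wall |
|-----------------|------------------------------------------------------|--------------|-------------|
| direct_access   | box through the distal surface, 3.0 wide, z 2.25–5.0 | 3.50         | thickest    |
| horizontal_slot | wide shallow channel, 5.5 wide, z 2.75–4.75          | 3.50         | thick       |
| vertical_slot   | tall narrow channel, 2.0 wide, z 1.75–6.0            | 3.00         | thinner     |
| occlusal_distal | distal box (2.5 wide, z ≥ 2.75) + occlusal step      | 2.75         | thinnest    |

`floor_x` is the mesiodistal position of the cavity floor; the remaining
dentin wall over the pulp (pulp reaches x = 2.0 at its equator) is the main
control on how fast heat reaches the pulp. Dimensions were calibrated once
with `scripts/calibrate_volumes.py` so that at 0.125 mm resolution the
composite volumes land on the published magnitudes — direct access
12.2 mm³ (±2 %), occlusal–distal 29.35 mm³ (±2 %), slots within 1 mm³ of
each other — and are not revisited. All cavity planes sit on the 0.25 mm
lattice of the crown bounding box, so measured volumes agree across the
0.25 and 0.125 mm grids to well under 5 %.

Carving refuses designs that would intersect the pulp or come closer than
`wall_margin` (default 0.5 mm, measured by Euclidean distance transform),
and designs that remove nothing.

## Discretization and time stepping

Two-point-flux finite volume on the voxel grid: face conductance
`G = k_harm A / d` with the harmonic mean `k_harm = 2 k₁k₂/(k₁+k₂)` (the
exact series conductance of two half-cells), `A = h²`, `d = h`. Storage is
lumped (`ρ c h³` per cell). The conduction matrix is symmetric with zero
row sums; adding the Robin diagonal makes it diagonally dominant, so the
implicit systems are symmetric positive definite.

The source temperature is imposed by row substitution on composite voxels
that own an exterior source face; the free-dof system is reduced once and
its matrix factorized once (sparse LU), since with a fixed step the matrix
never changes — each of the 300 default steps is then two triangular
solves. Preconditioned conjugate gradients (Jacobi, relative residual
1e-8) is available as an alternative and agrees with the direct path to
1e-4 °C in tests.

Default scheme is backward Euler with dt = 0.05 s (300 steps over 15 s):
unconditionally stable and satisfying a discrete maximum principle, so all
temperatures stay in [37, 140] °C. Crank–Nicolson is available for
accuracy comparisons but may oscillate on the ramp's kink; the analysis
module's earliest-crossing rule handles non-monotone traces.

Validation against closed forms (also exposed as `pulptherm validate`):

* sudden-step heating of a homogeneous half-space matches
  `T = T₀ + (T_s−T₀) erfc(x/2√(αt))` to 0.08 % relative L∞ at
  h = 0.05 mm, dt = 5 ms (distance measured from the held voxel center,
  which is where the discrete Dirichlet plane sits);
* steady conduction between two held faces reproduces the linear profile
  to machine precision;
* assembly equals a brute-force face-by-face oracle on random labelled
  grids.

## Sensors and threshold analysis

Probe placement inside each tissue is genuinely ambiguous, so two traces
are recorded per tissue at every time step: the tissue-wise maximum and a
fixed probe voxel nearest the cavity-floor centroid. The threshold
analysis defaults to the pulp *maximum* trace — the conservative choice
for a safety recommendation; the probe trace is retained for sensitivity
analysis (`sensor_mode="probe"`).

The crossing time t₄₂.₅ is computed by fitting `T = a + b t` exactly
through the first sample pair bracketing the threshold
(`b = (T₂−T₁)/(t₂−t₁)`, `a = T₁ − b t₁`) and inverting at
`T_crit = 42.5 °C`: `t = (T_crit − a)/b`. If the first sample already
exceeds the threshold its time is returned; a trace that never reaches it
yields a not-reached flag. For non-monotone traces the earliest upward
crossing is used.

The comparative summary tabulates, per design, the composite volume, the
crossing time, the peak pulp temperature, and a recommended safe dry
finishing duration: `floor(t_cross − margin)` seconds with margin 0 by
default (i.e. round the crossing time down to whole seconds); the margin
is configurable because published safe-duration recommendations sometimes
round more aggressively without stating a rule.

## Numerical choices and tie-breaks

* Linear solver tolerance (CG path) 1e-8 relative; direct path exact.
* dt must divide the total time; the protocol temperature is evaluated at
  the *end* of each step (fully implicit convention).
* `time_to_threshold` uses `T_i ≤ T_crit < T_{i+1}`, so a sample exactly
  at threshold is treated as already crossed at that sample.
* `max_temperature` returns the earliest time attaining the maximum.
* Degenerate inputs raise typed errors (`errors.py`) rather than
  propagating NaNs; non-finite temperatures abort the run.

## Problem sizes

The package's study configuration is 0.25 mm voxels (≈ 40 000 tissue
cells) and dt = 0.05 s; the four-design comparison completes in about
three minutes on one core. Volume calibration is checked at 0.125 mm;
analytic validation uses 1-D bars at 0.05–0.1 mm. These sizes are the
package's own desk-scale choices: halving voxel size and step changes the
end-time pulp temperature by a decreasing sequence (observed in tests), so
results at this scale are qualitatively converged.

## Known limitations

* Absolute crossing times and peak temperatures depend on the idealised
  phantom geometry; only the cross-design ordering and the inverse
  volume–time relation should be carried over to real teeth.
* The enamel offset is approximate (scaled semi-axes), so the shell is
  slightly thicker along diagonals.
* Dirichlet-by-substitution places the discrete source plane at composite
  voxel centers, an O(h) geometric bias that vanishes under refinement.
* Convection below the cervical plane is ignored entirely; with
  h = 3 W/(m²·K) convection is a weak sink regardless.
* No thermal-dose accumulation (e.g. CEM43); the threshold criterion is a
  single temperature crossing.
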