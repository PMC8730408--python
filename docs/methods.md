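# Methods

`mavessel` simulates whole blood flowing through capillary-scale channels
that carry a saccular microaneurysm (MA), using dissipative particle
dynamics (DPD) with explicitly resolved cells, and reduces the trajectories
to the two transport statistics that matter for intraluminal thrombosis:
how often platelets enter the MA body per passage, and how long they stay.

## The blood model

**Plasma.** Solvent particles interact through the standard DPD triplet
F = F^C + F^D + F^R with conservative weight (1 − r/r_c), dissipative
weight w_D = w_R², random weight w_R = (1 − r/r_c)^s, and the
fluctuation–dissipation constraint σ² = 2γk_BT per type pair.  Defaults:
a = 25, γ = 4.5, r_c = 1, k_BT = 1, s = 0.25 (the soft-matter choice that
raises viscosity relative to s = 1), solvent density 3 per cubic model
length.  Viscosity is only required to be self-consistent within the model;
no transport-coefficient matching to real plasma is attempted.  Random
forces use unit-variance uniform noise from a counter-based hash of
(seed, step, i, j), which makes them pairwise symmetric by construction,
evaluation-order independent and trivially resumable.

**Red blood cells.** Each RBC is a closed triangulated network of N_v = 500
membrane particles (66 in the desk-scale flow fixtures).  Its free energy
is V_t = V_s + V_b + V_a + V_v:

* *In-plane elasticity V_s*: per edge, a worm-like-chain attraction with
  maximum extension l_m = l_0/x_0 (x_0 = 1/2.2) plus a power-law repulsion
  (exponent m = 2) balancing it at the built edge length, so the built
  shape is the stress-free reference.
* *Bending V_b*: k_b(1 − cos(θ − θ_0)) per adjacent-triangle pair, with
  the spontaneous angles frozen from the built shape and
  k_b = 2k_0/√3 mapping the continuum bending rigidity
  k_0 = 2.4×10⁻¹⁹ J onto the triangulated sheet.
* *Area and volume constraints V_a, V_v*: quadratic global penalties
  k_a(A−A_0)²/2A_0 and k_v(V−V_0)²/2V_0 plus a local per-triangle area
  term (k_a = k_v = 4900, k_d = 100), targeting A_0 = 132.9 µm² and
  V_0 = 92.5 µm³ (reduced volume 0.64).

All forces are the exact analytic negative gradients of these energies
(finite-difference-verified to < 10⁻⁴ relative).  The network parameters
are calibrated to the macroscopic shear modulus µ_0 = 4.73 µN/m through
the closed-form small-strain relation for a hexagonal WLC+POW network,

    µ0 = (√3 kT / (4 p l_m x0)) (x0/2(1−x0)³ − 1/4(1−x0)² + 1/4)
       + 3√3 k_p / (4 l0³),

solved for the persistence length p (both terms scale as 1/p, so the
calibration is exact).  The diabetic preset stiffens µ by 5×.

**Platelets.** Oblate spheroids of volume 6 µm³ and aspect ratio 0.38
(thickness/diameter), meshed with exactly N_v = 48 vertices on latitude
rings whose pole vertices and antipodal equatorial pairs make the bounding
extents report the analytic dimensions exactly.  Their moduli are 100× the
RBC values — the rigid limit — and they are integrated as rigid bodies: at
every step the template shape is re-fitted to the vertex cloud (Kabsch)
and vertex velocities are projected onto rigid motion, conserving linear
and angular momentum.  This is both the physically intended behavior and a
necessity: explicit integration of the 100×-stiff network is unstable at
the fluid time step.

**Cell–cell and cell–fluid coupling.** RBC–RBC adhesion (high-fibrinogen
rouleaux regime) uses a Morse potential
V_M(r) = D_e[e^{2β(r0−r)} − 2e^{β(r0−r)}] between vertices of distinct
RBCs, every vertex adhesive; defaults D_e = 4 k_BT, β = 8.5 µm⁻¹,
r_0 = 0.5 µm, r_cut = 1.4 µm (tail < 10⁻³ D_e), chosen together with a
softened RBC–RBC conservative core (a = 25) so that a resting doublet
aggregates and flow disaggregates it.  Platelets adhere to nothing.
Solvent couples to membrane vertices through dissipative+random DPD
(no-slip at the membrane); impermeability is geometric: each solvent
particle's step segment is tested against nearby membrane faces in the
face's co-moving frame (the face translation over the step is subtracted,
so a face sweeping past a slow particle is still detected), and crossings
reflect specularly off the face with the impulse delivered to the face's
vertices by barycentric weights.  The face-relative exit speed is capped
at 4√(k_BT) — without the cap a particle trapped in a closing gap between
membranes Fermi-accelerates.  Non-bonded vertex pairs of the same cell
repel below 0.8 µm (well under the bonded spacing), so a folded membrane
cannot pass through itself.

## Channel geometry and driving

The parent vessel is a rectangular duct, width R₂ = 5 µm (y), depth 10 µm
(z), periodic along the flow (x).  The MA body is a sphere of diameter
R₁ = BNR·R₂ truncated by the wall plane y = R₂ and centered
√((R₁/2)² − (w_n/2)²) above it, so the circular neck opening cut by the
wall plane has exactly the requested width w_n (15 µm, clamped to R₁ for
the smallest body).  The lumen is the union duct ∪ {sphere, y ≥ R₂}; the
neck disk is the event-detection surface.  Walls combine a frozen-particle
shell (thickness ≥ r_c, density 2) carrying DPD friction with a sliding
specular reflection of any mobile particle that leaves the lumen —
reflecting only the wall-normal motion lets membrane vertices slide along
the wall instead of tearing their own mesh.

Flow is driven by a uniform body force on solvent in the parent duct
(equivalent to a pressure gradient under periodicity), tuned by a
velocity-form proportional–integral controller to the target mean inlet
velocity measured in a probe slab one vessel-width upstream of the neck.
Pulsatile mode scales the force by 1 + A sin(2πt/T) (A = 0.3, T = 1 s
mapped through the unit system), which time-averages to exactly 1.

## Units

1 model length = 1 µm; 1 model energy = k_BT at 310 K; mass scale
6.85×10⁻¹⁶ kg, making 1 model velocity = 2.5 mm/s and 1 model time =
0.4 ms.  This places the physiological inlet velocities (0.25–2 mm/s) at
0.1–0.8 model units: below the thermal velocity (DPD stability) but far
above the exaggerated coarse-grained diffusion, i.e. a realistically large
Peclet number — at desk scale the trends would otherwise drown in thermal
wandering that real micron-scale cells do not exhibit.

## Numerical choices

* Integration: velocity-Verlet with the dissipative force evaluated at the
  mid-step velocity (λ = 1/2); dt = 0.01 model time.  dt ≥ 0.0125 is
  unstable for the membrane system (verified across seeds).
* Mesh edges carry a unit-weight bonded-pair thermostat (γ = 15, σ
  matched): bonded neighbors of coarse meshes lie beyond the fluid cutoff,
  so the distance-weighted DPD thermostat would leave membrane oscillation
  modes undamped.  This is numerical damping with correct thermal balance,
  not a membrane-rheology model.  γ = 30 is marginally unstable at
  dt = 0.01; 15 is validated across seeds.
* The WLC tension plateaus at 4.5 k_BT/p per edge inside the driver loop
  (a momentum-conserving safeguard against rare overstretched transients);
  the public force API keeps the exact divergent form.
* Neighbor search: half-cutoff binned Verlet list with skin 0.5, rebuilt
  when the two largest displacements sum past 0.9·skin (a pair can close
  by at most that sum).
* Cells are seeded face-on to the flow, pre-compressed along the duct
  width when wider than the duct, with all membrane stiffnesses ramped
  linearly over the equilibration window; hematocrit counts reference
  volumes (N = round(Ht·V_region/V_0), parent duct for parent seeding).
* Instability detection aborts a run when any |v| exceeds 150 (thermal
  tails with reflection impulses reach ~40; true blowups exceed 10³
  within tens of steps).

## Transport statistics

Cell tracks record the unwrapped center of mass and lumen region every
25 steps.  An entry is a center-of-mass classification into the body for
at least 3 consecutive frames (debouncing boundary jitter); its residence
time is the body-frame count times the frame interval.  A passage is one
channel traversal, counted from the cumulative downstream displacement in
units of the channel length with the odometer frozen while the cell is
inside the body.  Cells seeded inside the MA are excluded; cells still
inside at run end are censored and never mixed into residence means.
Entry probability is entries/passages with a bootstrap-over-cells CI.  The
perfused fraction (an operational summary of the qualitative perfusion
contrast) is the fraction of body voxels (2 µm) visited by parent-seeded
RBC centers.

## Desk scale: what the fixtures do and do not show

The study-scale runs (50M steps, hematocrit up to 40%, BNR 8) are
cluster-sized; the shipped presets reproduce their conditions but the test
suite runs desk-scale embodiments: true geometry ratios and physical drive
velocities, but solvent density 1 µm⁻³, coarse RBC meshes (N_v = 66),
18–24-µm channels and runs of 3–6×10³ steps, five seeds per condition
with passages pooled across seeds.  At this scale absolute probabilities and
residence times are not comparable to the full-scale study — only
orderings across conditions are asserted (larger BNR, faster inlet flow,
higher hematocrit and RBC adhesion each promote platelet entry; platelets
outstay RBCs; small-BNR bodies perfuse more completely).  The synthetic
scenarios also idealize real microvasculature: rigid straight walls, a
single MA, no platelet–wall adhesion or coagulation chemistry (explicitly
out of scope), and a sinusoidal stand-in for the cardiac waveform.

## Known limitations

* Membrane impermeability is not exact for the thermally deforming coarse
  membrane: the co-moving-frame crossing test captures face translation
  but not within-step face rotation/deformation, leaving a residual miss
  rate of a few tenths of a percent per reflection event.  The scheme is
  verified exactly watertight for static and rigidly translating
  membranes; against a driven deforming cell the enclosed solvent count
  stays roughly steady while cytosol identity exchanges on a ~5×10³-step
  time scale.  An exact treatment needs swept-triangle (quadratic-in-time)
  intersection tests.
* The desk-scale trend statistics rest on tens of pooled passages per
  condition; individual orderings carry sampling noise.
* The bounce-back/specular wall hybrid leaves a small near-wall slip and
  density artifact, bounded by the duct-profile validation (< 10% RMS vs
  the analytic rectangular-duct series).
* Rigid-body platelets cannot report platelet deformation (negligible by
  construction at 100× moduli).
* Several microscopic coefficients (DPD amplitudes, penalty strengths,
  Morse constants) have no single authoritative experimental value; the
  defaults here follow standard mesoscale-blood-modeling practice and are
  all exposed in the configuration.
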