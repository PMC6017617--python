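# Methods

## The potential model

`polmem` evaluates a polarizable atomic-multipole potential of the
AMOEBA family for fixed configurations. Internal units are Å, e, e·Å,
e·Å² and kcal/mol throughout; Debye (1 e·Å = 4.803205 D) and Volt
(1 kcal·mol⁻¹·e⁻¹ = 0.0433641 V) appear only at reporting boundaries.
The Coulomb factor is 332.0637 kcal·Å·mol⁻¹·e⁻².

### Permanent electrostatics

Each site carries a charge q, dipole μ and **traceless second-moment
quadrupole** Q = Σ q_k (d_k d_kᵀ − |d_k|²I/3). Under this convention the
site potential is

φ(r) = q/r + μ·r̂/r² + (3/2) r̂ᵀQr̂ / r³,

and pair energies are formed as U = q_i φ_j + μ_i·∇φ_j + ½ Q_i:∇∇φ_j,
i.e. through quadrupole–quadrupole order. Input quadrupoles are
symmetrized and detraced on construction (warning above 1e-6 e·Å²) —
rotations and uniform scalings then preserve tracelessness exactly.
The tensor algebra is locked in by tests against an independent
finite point-charge-cluster oracle whose moments match by construction
and whose Coulomb sums run in 60-digit decimal arithmetic (the cluster
charges grow as 1/h², so double precision cancels catastrophically
below h ≈ 1e-3 Å).

Multipoles are stored in local frames built from bonded anchors
(z-then-x, bisector, z-only for terminal sites, none for monatomic
ions). The z-axis points from the owning site **toward** its z-anchor;
collinear anchors are a hard error, never a silent fallback. Anyone
importing genuine TINKER files should check the sign convention of
their source — it is not stated uniformly in the literature.

Connectivity scaling for permanent electrostatics is 0.0/0.0/0.4/0.8
for 1-2/1-3/1-4/1-5 pairs, vdW uses 0/0/1/1; both live in
`ForceFieldConfig` and are overridable. Direct-space pairwise summation
only, with minimum-image wrapping when an orthorhombic box is supplied;
Ewald/PME belongs to MD engines and is out of scope, as are analytic
gradients (nothing here minimizes or integrates).

### Induction

Induced dipoles solve μ_i = α_i(E_i^perm + Σ_j T_ij μ_j)
self-consistently. The permanent field excludes sources in the same
polarization group (groups are connected components after cutting
rotatable bonds); mutual dipole coupling acts between all polarizable
sites. Thole damping uses the exponential smearing ρ ∝ exp(−a·u³) with
u = r/(α_iα_j)^{1/6} and a single global width a = 0.39 (per-type
widths were considered and rejected for lack of any basis to assign
them; the value is configurable). The solver is Jacobi iteration with
successive over-relaxation ω = 0.7 — plain Jacobi can oscillate at high
polarizability density, and ω = 0.7 damps this without materially
slowing converging cases. Convergence is the maximum per-site dipole
change falling below 1e-5 D (default; configurable), with a hard
iteration budget (100) whose exhaustion raises an error carrying the
last change rather than returning silently. The fixed point is checked
against a dense 3N×3N linear solve in the tests. The polarization
energy is U = −½ Σ μ_i·E_i^perm, non-positive for non-negative α.

### Bonded terms and vdW

Bond stretching uses the quartic Morse expansion
k·Δ²(1 + c₃Δ + c₄Δ²) with c₃ = −2.55 Å⁻¹, c₄ = 3.793125 Å⁻²; angles and
Wilson–Decius–Cross out-of-plane bends use the sextic polynomial with
d₃ = −0.014, d₄ = 5.6e-5, d₅ = −7e-7, d₆ = 2.2e-8 (per degree^n). These
are the standard constants of the force-field family; following the
convention under which they are quoted, the leading quadratic takes Δθ
in radians while the correction polynomial takes degrees. Stretch-bend
coupling uses a single constant per angle, k_sb(Δr_ij + Δr_kj)Δθ_rad.
Torsions are the six-term Fourier series Σ (V_n/2)(1 + cos(nφ − γ_n)),
phases restricted to {0°, 180°}.

Van der Waals is Halgren's buffered 14-7 with δ = 0.07, γ = 0.12;
U(r_min) = −ε exactly. Pair parameters combine by cubic-mean r_min and
HHG ε. Hydrogen interaction centers are displaced toward their bonded
heavy atom by the per-class reduction factor before any distance is
evaluated. Angles at exactly 0°/180° and coincident sites raise typed
errors.

## Parameterization operations

**ESP fitting.** The model potential is linear in the multipole
components once local frames are fixed, so each fitting stage is solved
as an exact constrained linear least-squares problem rather than by
iterative descent — the named "gradient convergence criterion"
(0.5 / 0.1 / 0.01 kcal·mol⁻¹·e⁻² for the fragment / merged-headgroup /
tail stages of the published workflow) is applied to the RSS gradient:
an initial guess already below it is returned untouched (iterations 0),
and a solved stage satisfies it by construction. The net-charge
constraint is imposed by eliminating the last free charge;
tracelessness is built into the 5-component quadrupole
parameterization. Rank-deficient designs raise an error carrying the
null-space directions instead of silently regularizing. Grid points
must stay outside a 1 Å exclusion shell around every site.

The fit design uses permanent multipoles only. Fragments are
parameterized as single polarization groups, where intramolecular
induction vanishes identically; for evaluation (`esp_at_points`,
`molecular_dipole`) induced dipoles can be added explicitly.

**Merging and post-fit adjustments.** Fragment sets are merged by an
explicit atom correspondence; unmapped merged sites are cap groups and
carry zero multipoles, and the residual between the summed monopoles
and the declared net charge is spread **equally over heavy atoms** so
charge is conserved to 1e-12 e. Quadrupole scaling (e.g. the 0.6 factor
conventionally applied to hydroxyl groups after fitting) multiplies the
selected tensors element-wise; "scaled by 60%" is read as ×0.6, not
−60% — the switchable factor makes the other reading available.

**Torsion fitting.** The target is ΔE(φ) = E_ref − E_model(no torsion)
on a scan grid (canonically 30° spacing). With phases fixed the fit is
linear and solved exactly; a constant offset is always included because
conformational-energy zeroes are arbitrary. Scans are fit
per-dihedral; unweighted least squares (no high-energy deweighting).
Aliased grids (e.g. 45° spacing, where cos3φ ≡ cos5φ) raise a rank
report. Fit quality is summarized by OLS slope/intercept, Pearson R²,
RMS residual and mean unsigned error on relative energies (each scan
shifted to min = 0).

## Bilayer observables

The bilayer normal is +z; boxes are orthorhombic; coordinates are
wrapped into [0, L_z) and binned into half-open uniform slabs (default
100 — fine enough that parabolic peak refinement works, coarse enough
that slabs stay populated). The midplane is the mean z of the
terminal-methyl carbons; leaflets split there.

* **A_L, V_L** are exact arithmetic per frame, then time-averaged;
  V_w defaults to 30.53 Å³ per water molecule.
* **Electron density** assigns each atom Z − q electrons (permanent
  monopole only; dipole/quadrupole contributions are not counted), so
  group profiles sum to the total and slab-integrals conserve the
  electron count exactly. D_HH is the distance between the two density
  peaks on opposite sides of the midplane with parabolic sub-bin
  refinement; a profile without a peak on each side raises an error.
  On the synthetic bilayer the phosphate-group profile is the right
  peak source (see the generator's limitations below).
* **S_CD** averages (3cos²θ − 1)/2 over the C–H bonds of each chain
  carbon (hydrogens standing proxy for deuterium, the simulation
  convention), lipids and frames.
* **Headgroup tilt** is measured against the *outward* leaflet normal
  (+z upper, −z lower), binned over [0°, 180°], density normalized to
  integrate to 1 per degree; the modal angle is reported.
* **Dipole potential**: per slab, E_z is the arithmetic mean of
  μ_ind,z/α over the polarizable atoms in the slab (α = 0 atoms
  excluded), ensemble-averaged over frames; slabs never populated are
  linearly interpolated from neighbours and flagged. φ(z) accumulates
  by the trapezoid rule from z = 0, i.e. from the box edge in bulk
  water, so that Δφ = φ(bilayer center) − ⟨φ⟩_water-plateau is
  referenced to water; the plateau is the set of water-dominated slabs
  (≥90 % water atoms), falling back to the outer 5 % of slabs. Whether
  water atoms should enter the E_z estimator is genuinely ambiguous;
  all polarizable atoms are included by default and the composition's
  polarizability vector makes any selection expressible.

## Synthetic fixtures

Every generator is a pure function of its spec — same seed, identical
output — and fixture files record their seed in the header/title.

* `gen_toy_molecule` builds 2–12-site zig-zag hetero-chains with
  element-typed polarizabilities and vdW parameters, valid non-collinear
  local frames, traceless random multipoles, near-equilibrium bonded
  parameters, and net charge 0 or −1 (the charge states of lipid
  headgroup fragments). Additional conformers come from rigid rotation
  about an interior bond, which is what makes multi-conformer ESP
  fitting non-trivial.
* ESP grids are Connolly-style: four offset shells at 1.0–2.0 × the
  vdW radius, ≈1 point/Å² at full density, everything inside the
  innermost shell or 1 Å of a site discarded. (Published workflows
  rarely state their grid construction; this is the community default,
  not a claim of equivalence.)
* `gen_bilayer_traj` emulates the 72-lipid validation systems: two
  leaflets on a jittered lateral grid, phosphate planes ±17 Å from the
  midplane, per-lipid net charge −1 balanced by one Na⁺ placed near
  each phosphate, lateral box 46.5 ± 0.3 Å (A_L ≈ 60 Å²), and a water
  count chosen so V_L lands near 1020 Å³. Chain C–H directions are
  drawn from a mixture (aligned/in-plane vs. isotropic) whose
  expectation equals the prescribed S_CD exactly, so the analyzer
  recovers the target within Monte Carlo error. Induced dipoles can be
  manufactured as μ = α·E*(z) from a prescribed field profile, giving
  the dipole-potential estimator a known integral to recover.

What the generator does **not** emulate: real intramolecular structure
(waters are single pseudo-atoms of 10 electrons; chains have no
torsional correlation), undulations, area–thickness coupling, and any
genuine Boltzmann sampling. Passing analyses therefore demonstrate the
estimators' correctness — binning, normalization, unit conversions,
conservation laws — not force-field accuracy against experiment. In
particular the sparse pseudo-headgroup means the *total* electron
density peaks in the water plateau, which is why D_HH is read from the
phosphate profile on these fixtures.

## Problem sizes and numerics

Tests and the acceptance script use desk-scale systems chosen as the
smallest sizes that exercise every code path: ≤ 6-site systems for
oracle comparisons (clusters of 16 charges per multipole; h down to
1e-4 Å), 24–72-lipid bilayers with a few thousand atoms and ≤ 25
frames, and 10⁶ Monte Carlo draws for the isotropic order-parameter
null (standard error ≈ 0.0007). Uncertainties on per-lipid quantities
are reported as plain time standard deviations.

## Known limitations

* No Ewald summation: periodic electrostatics beyond minimum image is
  out of scope, so absolute energies of dense periodic systems are not
  comparable to PME-based engines.
* No gradients/forces; validation is purely energetic.
* The key-file dialect stores multipoles in e·Å/e·Å² rather than
  TINKER's atomic-unit convention, and the multipole frame encoding
  (negative z-class ⇒ bisector) is this dialect's rule — files are not
  interchangeable with TINKER without conversion.
* Chirality-sensitive (y-flip) frame variants and multipoles beyond
  quadrupole are not implemented.
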