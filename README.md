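# polmem

Polarizable atomic-multipole potentials and membrane-bilayer observables
for anionic-lipid force-field work.

## What this is for

Fixed-charge lipid force fields cannot represent how a molecule's charge
distribution responds to the very different dielectric environments on
the two sides of a membrane interface — bulk water outside, a low-dielectric
hydrocarbon core inside. Polarizable models of the AMOEBA family address
this by giving every atom a permanent **monopole, dipole and quadrupole**
(stored in a bonded-neighbour local frame so parameters transfer across
conformations) plus an **induced dipole** μᵢ = αᵢEᵢ solved
self-consistently with Thole short-range damping.

`polmem` implements, as a tested Python library with a thin CLI:

1. **The potential model** — for a fixed configuration, every term of

   U = U_bond + U_angle + U_bθ + U_oop + U_torsion + U_vdW + U_ele^perm + U_ele^ind

   with quartic Morse-expansion bonds, sextic angles, stretch-bend and
   Wilson–Decius–Cross out-of-plane coupling, six-term Fourier torsions,
   Halgren's buffered 14-7 vdW with hydrogen reduction factors,
   Cartesian multipole electrostatics through quadrupole–quadrupole
   order, and Jacobi/SOR self-consistent induction
   (U_ele^ind = −½ Σᵢ μᵢ·Eᵢ^perm).

2. **Parameterization operations** — model ESP on off-molecule grids,
   staged multi-conformer least-squares multipole fitting (charges
   first, then dipoles/quadrupoles with charges frozen, at named
   gradient-convergence criteria), fragment merging with cap-group
   zeroing and equal spreading of the residual charge over heavy atoms,
   post-fit quadrupole scaling, and six-term Fourier torsion fits to
   QM-minus-model scan residuals.

3. **Bilayer observables** — from multi-frame trajectories: area per
   lipid A_L = LₓL_y/(n_lipid/2); volume per lipid
   V_L = (LₓL_yL_z − n_w·V_w)/n_lipid with V_w = 30.53 Å³; electron
   density profiles by the Z − q rule with group decomposition and
   head-to-head thickness D_HH; deuterium order parameters
   S_CD = ⟨3cos²θ − 1⟩/2 per chain carbon; headgroup tilt
   distributions; and the membrane dipole potential
   φ(z) = ∫₀ᶻ E_z dz with E_z estimated per slab from μ_ind,z/α.

Everything runs on deterministic synthetic fixtures generated by
`polmem.fixtures` — no external data needed.

## Worked example

```bash
python examples/04_bilayer_observables.py
```

```
72 lipids, 3258 waters, 4986 atoms, 8 frames
area per lipid:     60.21 ± 0.68 Å²
volume per lipid: 1026.95 ± 27.07 Å³ (V_w = 30.53 Å³ per water)
D_HH from the phosphate density peaks: 34.0 Å (generator places headgroups ±17.0 Å, so ≈ 34 Å is expected)
S_CD per chain carbon (negative: C–H bonds lie mostly in-plane):
  C2:-0.201  C3:-0.159  C4:-0.167  C5:-0.102  C6:-0.076  C7:-0.050  C8:-0.015
headgroup tilt mode: 92.5° from the outward normal (≈90°: the P→C2 vector lies in the membrane plane)
```

The synthetic bilayer emulates the standard 72-lipid validation setup:
the lateral box is drawn around 46.5 Å so A_L fluctuates near 60 Å², the
water count puts V_L near 1020 Å³, phosphate planes sit ±17 Å from the
midplane so the phosphate electron-density peaks are 34 Å apart, and
chain C–H vectors are sampled against a prescribed order-parameter
profile that the analysis recovers.

The other examples cover the remaining capabilities: `01` energy
breakdown with SCF induction, `02` staged ESP fitting with charge
freezing, merging and quadrupole scaling, `03` torsion fitting, and
`05` the dipole-potential estimator against a prescribed field.

The same operations are available from the shell:

```bash
polmem synth --kind molecule --seed 9 --out fix/
polmem energy --xyz fix/mol.txyz --key fix/mol.key --report json
polmem bilayer-analyze --traj fix/traj.arc --comp fix/comp.yaml \
    --obs area,volume,edp,scd,tilt --out obs/
```

## Scope

The library evaluates energies of given configurations and fits
parameters to externally supplied reference data. It deliberately does
**not** do quantum chemistry, molecular-dynamics propagation, or Ewald
summation (electrostatics is direct-space with minimum-image wrapping),
and it ships no published lipid parameter sets — fixtures are synthetic.
See `docs/methods.md` for the model details and design choices.
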