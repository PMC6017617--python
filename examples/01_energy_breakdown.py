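"""Evaluate every term of the polarizable potential for a small molecule.

Builds a deterministic 6-site toy fragment (chain geometry, permanent
multipoles in bonded local frames, polarizabilities, bonded and vdW
parameters) and prints the energy breakdown: anharmonic bonded terms,
buffered 14-7 vdW, permanent multipole electrostatics, and the
polarization energy of the self-consistent Thole-damped induced dipoles.
"""

from polmem import fixtures
from polmem.energy import induce_dipoles, total_energy
from polmem.mpole import rotate_to_global

system = fixtures.gen_toy_molecule(
    fixtures.ToyMoleculeSpec(seed=3, n_sites=6, net_charge=-1)
)
breakdown = total_energy(system)

print("Energy breakdown (kcal/mol) for the seed-3 anionic toy fragment:")
for name, value in breakdown.as_dict().items():
    print(f"  {name:12s} {value:12.6f}")

gset = rotate_to_global(system.local_multipoles, system.frames,
                        system.coords)
induced = induce_dipoles(system.sites, gset, system.topology)
print(f"\nSCF induction converged in {induced.iterations} iterations "
      f"(last change {induced.final_change_debye:.2e} D).")
print("U_ele_ind is negative: induced dipoles always lower the energy "
      "of the permanent field that created them.")
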