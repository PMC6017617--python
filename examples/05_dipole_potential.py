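"""Membrane dipole potential from induced dipoles.

The electrostatic potential profile across a bilayer is estimated by
inverting the induced-dipole definition per atom (E_z ≈ μ_ind,z/α),
averaging over slabs, and integrating from the bulk-water edge.  Here
the trajectory carries induced dipoles manufactured from a prescribed
interfacial field E*(z), so the recovered φ(z) can be compared with the
exact integral ∫E* dz.
"""

import numpy as np

from polmem import fixtures
from polmem.constants import COULOMB, VOLT_PER_KCAL_MOL_E
from polmem.membrane import dipole_potential


def efield(z, lz=80.0):
    """Antisymmetric interfacial field, e/Å²: positive lobe at the upper
    headgroup plane, negative at the lower."""
    mid = lz / 2
    return (0.002 * np.exp(-((z - mid - 17) ** 2) / 18.0)
            - 0.002 * np.exp(-((z - mid + 17) ** 2) / 18.0))


spec = fixtures.BilayerSpec(seed=2, n_frames=5, box_sigma=0.0,
                            efield=efield)
frames, comp = fixtures.gen_bilayer_traj(spec)
res = dipole_potential(frames, comp, n_slabs=100)

z = res.phi.z
estar = efield(z) * COULOMB
phi_star = np.concatenate(
    [[0.0], np.cumsum(0.5 * (estar[1:] + estar[:-1]) * res.phi.width)]
) * VOLT_PER_KCAL_MOL_E

err = np.abs(res.phi.values - phi_star).max()
print(f"max |φ_recovered − ∫E*dz| = {err:.4f} V "
      f"(profile magnitude {np.abs(phi_star).max():.3f} V)")
print(f"Δφ(water → bilayer center) = {res.delta_phi:+.3f} V")
print(f"interpolated empty slabs: {len(res.interpolated_slabs)}")
print("A negative Δφ here just reflects the sign of the prescribed "
      "field; the magnitude tracks the area under E*(z).")
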