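"""Structural observables of a lipid bilayer trajectory.

Generates a synthetic 72-lipid bilayer (the standard validation system
size) with fluctuating box, counter-ions and waters, and computes the
descriptors used to compare lipid force fields with experiment: area
and volume per lipid, the electron density profile and its head-to-head
peak distance D_HH, deuterium order parameters per chain carbon, and the
headgroup tilt distribution.
"""

from polmem import fixtures
from polmem.membrane import (
    area_per_lipid,
    bilayer_thickness,
    electron_density_profile,
    headgroup_angle_distribution,
    order_parameters,
    volume_per_lipid,
)

spec = fixtures.BilayerSpec(seed=7, n_frames=8)
frames, comp = fixtures.gen_bilayer_traj(spec)
print(f"{comp.n_lipid} lipids, {comp.n_water} waters, "
      f"{comp.n_atoms} atoms, {len(frames)} frames")

a_mean, a_sd = area_per_lipid(frames, comp)
v_mean, v_sd = volume_per_lipid(frames, comp)
print(f"area per lipid:   {a_mean:7.2f} ± {a_sd:.2f} Å²")
print(f"volume per lipid: {v_mean:7.2f} ± {v_sd:.2f} Å³ "
      "(V_w = 30.53 Å³ per water)")

profiles = electron_density_profile(frames, comp, n_slabs=100)
d_hh = bilayer_thickness(profiles["PO4"])
print(f"D_HH from the phosphate density peaks: {d_hh:.1f} Å "
      f"(generator places headgroups ±{spec.head_offset} Å, so ≈ "
      f"{2 * spec.head_offset:.0f} Å is expected)")

s_cd = order_parameters(frames, comp)["sn1"]
print("S_CD per chain carbon (negative: C–H bonds lie mostly in-plane):")
print("  " + "  ".join(f"C{c}:{v:+.3f}" for c, v in sorted(s_cd.items())))

_, mode = headgroup_angle_distribution(frames, comp)
print(f"headgroup tilt mode: {mode:.1f}° from the outward normal "
      "(≈90°: the P→C2 vector lies in the membrane plane)")
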