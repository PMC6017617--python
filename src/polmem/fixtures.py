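"""Deterministic synthetic fixtures.

Every generator is a pure function of its spec (same seed → identical
output), giving each analysis and parameterization operation a testable
input without any external data:

* :func:`gen_toy_molecule` — a small zig-zag hetero-chain (2–12 sites)
  with plausible geometry, valid local frames, traceless multipoles,
  polarizabilities and bonded/vdW parameters, net charge 0 or −1
  (the fragment charges occurring in lipid headgroup parameterization);
* :func:`gen_conformers` — additional conformers of the toy molecule
  made by rotating about an interior bond;
* :func:`gen_esp_grid_points` — Connolly-style shells of off-molecule
  grid points (4 offset shells at 1.0–2.0 × vdW radii, ≈1 point/Å²);
* :func:`gen_torsion_scan` — a dihedral scan whose QM-minus-model
  residual comes from known Fourier amplitudes;
* :func:`gen_bilayer_traj` — a coarse two-leaflet pseudo-lipid bilayer
  with waters and counter-ions, chain C–H vectors drawn to match a
  prescribed order-parameter profile, fluctuating box, per-atom
  charges/Z/α, and optional induced dipoles μ = α·E*(z) from a
  prescribed field profile.

The bilayer emulates the published study conditions (72 lipids, two
leaflets, headgroup peaks ≈ 34 Å apart, area per lipid ≈ 60 Å²); it is
a geometric stand-in for an MD trajectory, not a simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .energy import BondedParams, System, VdwParams
from .mpole import LocalFrameDef, Multipole, MultipoleSet, PolarizableSite
from .membrane import BilayerComposition, TrajectoryFrame
from .topology import Topology
from .torsion import FourierFit, TorsionScan
from .constants import ATOMIC_NUMBERS

__all__ = [
    "ToyMoleculeSpec", "BilayerSpec",
    "gen_toy_molecule", "gen_conformers", "gen_esp_grid_points",
    "gen_torsion_scan", "gen_bilayer_traj", "toy_molecule_keyfile",
]

# element → (polarizability Å³, vdW rmin Å, vdW eps kcal/mol)
_ELEMENT_TABLE = {
    "H": (0.496, 2.98, 0.024),
    "C": (1.334, 3.82, 0.101),
    "N": (1.073, 3.71, 0.110),
    "O": (0.837, 3.30, 0.112),
    "P": (1.828, 4.45, 0.200),
    "Na": (0.120, 3.02, 0.260),
}

_VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80,
              "Na": 2.27}

_CHAIN_ELEMENTS = "CONCPCOCNCOC"


@dataclass(frozen=True)
class ToyMoleculeSpec:
    seed: int = 0
    n_sites: int = 6
    net_charge: int = 0          # 0 or −1, like the headgroup fragments
    polarizable: bool = True


def gen_toy_molecule(spec: ToyMoleculeSpec) -> System:
    """Build a deterministic toy molecule as a full :class:`System`."""
    n = spec.n_sites
    if not (2 <= n <= 12):
        raise ValueError("toy molecule supports 2–12 sites")
    if spec.net_charge not in (0, -1):
        raise ValueError("net charge must be 0 or −1")
    rng = np.random.default_rng(spec.seed)

    elements = [_CHAIN_ELEMENTS[i % len(_CHAIN_ELEMENTS)] for i in range(n - 1)]
    elements.append("H")
    # zig-zag backbone, bond length ≈ 1.5 Å, plus a small jitter
    coords = np.zeros((n, 3))
    for i in range(1, n):
        step = np.array([1.35, 0.65 * (-1) ** i, 0.15])
        coords[i] = coords[i - 1] + step + rng.normal(0, 0.03, 3)

    bonds = [(i, i + 1) for i in range(n - 1)]
    rotatable = [(i, i + 1) for i in range(1, n - 2, 2)]
    topo = Topology(n, bonds, rotatable)

    sites = []
    for i, el in enumerate(elements):
        alpha, _, _ = _ELEMENT_TABLE[el]
        sites.append(PolarizableSite(
            index=i, element=el, atomic_number=ATOMIC_NUMBERS[el],
            position=coords[i],
            polarizability=alpha if spec.polarizable else 0.0,
            type_class=i + 1,
        ))

    # local frames: z toward the previous neighbour, x toward the next
    frames: list[LocalFrameDef] = []
    for i in range(n):
        if n == 2:
            frames.append(LocalFrameDef("z_only", anchor_z=1 - i))
        elif i == 0:
            frames.append(LocalFrameDef("z_then_x", anchor_z=1, anchor_x=2))
        elif i == n - 1:
            frames.append(LocalFrameDef("z_then_x", anchor_z=n - 2,
                                        anchor_x=n - 3))
        else:
            frames.append(LocalFrameDef("z_then_x", anchor_z=i - 1,
                                        anchor_x=i + 1))

    charges = rng.uniform(-0.3, 0.3, n)
    charges += (spec.net_charge - charges.sum()) / n
    mpoles = []
    for i in range(n):
        dip = rng.normal(0.0, 0.05, 3)
        raw = rng.normal(0.0, 0.03, (3, 3))
        quad = 0.5 * (raw + raw.T)
        quad -= np.trace(quad) / 3.0 * np.eye(3)
        mpoles.append(Multipole(float(charges[i]), dip, quad))
    local = MultipoleSet(mpoles, "local")

    bonded = BondedParams()
    for i, j in bonds:
        r = float(np.linalg.norm(coords[j] - coords[i]))
        bonded.bonds.append((i, j, float(rng.uniform(300, 450)),
                             r - float(rng.uniform(0.0, 0.02))))
    for j in range(1, n - 1):
        u, v = coords[j - 1] - coords[j], coords[j + 1] - coords[j]
        theta = math.degrees(math.acos(np.clip(
            u @ v / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))
        bonded.angles.append((j - 1, j, j + 1, float(rng.uniform(40, 80)),
                              theta - float(rng.uniform(0.0, 2.0))))
        bonded.stretch_bends.append((j - 1, j, j + 1, float(rng.uniform(3, 8))))
    for i in range(n - 3):
        amps = tuple(float(a) for a in rng.uniform(-1.0, 1.0, 6))
        phases = tuple(float(p) for p in rng.choice([0.0, 180.0], 6))
        bonded.torsions.append((i, i + 1, i + 2, i + 3, amps, phases))

    vdw = VdwParams(
        eps={s.type_class: _ELEMENT_TABLE[s.element][2] for s in sites},
        rmin={s.type_class: _ELEMENT_TABLE[s.element][1] for s in sites},
        reduction={s.type_class: 0.92 for s in sites if s.element == "H"},
    )
    return System(sites, topo, local, frames, bonded, vdw)


def gen_conformers(
    system: System, angles_deg: Sequence[float]
) -> dict[str, np.ndarray]:
    """Extra conformers by rotating the tail of the chain about an
    interior bond; conformer "c0" is the original geometry."""
    coords0 = system.coords
    n = len(system.sites)
    out = {"c0": coords0.copy()}
    if n < 4:
        for k, _ in enumerate(angles_deg, start=1):
            out[f"c{k}"] = coords0.copy()
        return out
    j, k = 1, 2          # rotate everything past site 2 about bond 1-2
    axis = coords0[k] - coords0[j]
    axis = axis / np.linalg.norm(axis)
    for idx, ang in enumerate(angles_deg, start=1):
        t = math.radians(ang)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * K @ K
        c = coords0.copy()
        for m in range(k + 1, n):
            c[m] = coords0[k] + R @ (coords0[m] - coords0[k])
        out[f"c{idx}"] = c
    return out


def gen_esp_grid_points(
    coords: np.ndarray,
    elements: Sequence[str],
    seed: int = 0,
    shells: Sequence[float] = (1.0, 1.333, 1.666, 2.0),
    density_per_a2: float = 1.0,
) -> np.ndarray:
    """Connolly-style grid: points on concentric offset shells around each
    atom at multiples of its vdW radius, keeping only points outside the
    innermost shell of every atom (and at least 1 Å from every site)."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.array([_VDW_RADII.get(e, 1.7) for e in elements])
    points = []
    for scale in shells:
        for i, (c, rad) in enumerate(zip(coords, radii)):
            r = scale * rad
            n_pts = max(8, int(density_per_a2 * 4 * math.pi * r * r))
            v = rng.normal(size=(n_pts, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            cand = c + r * v
            d = np.linalg.norm(cand[:, None, :] - coords[None, :, :], axis=2)
            keep = np.all(d >= np.maximum(shells[0] * radii - 1e-9, 1.0), axis=1)
            keep &= np.all(d >= 1.0, axis=1)
            points.append(cand[keep])
    pts = np.vstack(points)
    if len(pts) == 0:
        raise RuntimeError("no grid points survived the exclusion filter")
    return pts


def gen_torsion_scan(
    seed: int,
    amplitudes: Sequence[float],
    offset: float = 0.0,
    phases: Sequence[float] = (0.0,) * 6,
    angles: Sequence[float] | None = None,
    noise_sigma: float = 0.0,
    dihedral: str = "synthetic",
) -> TorsionScan:
    """Scan whose QM−model residual is an exact known Fourier series
    (plus optional Gaussian noise): the parameter-recovery fixture."""
    rng = np.random.default_rng(seed)
    ang = (np.arange(0.0, 360.0, 30.0) if angles is None
           else np.asarray(angles, dtype=float))
    truth = FourierFit(tuple(amplitudes), tuple(phases), offset, 0.0)
    delta = truth.predict(ang)
    # a smooth synthetic torsion-free model profile
    phi = np.radians(ang)
    e_mm = (rng.uniform(0.5, 2.0) * np.cos(phi + rng.uniform(0, 2 * math.pi))
            + rng.uniform(0.0, 1.0))
    e_qm = e_mm + delta + rng.normal(0.0, noise_sigma, len(ang))
    return TorsionScan(dihedral, ang, e_qm, e_mm)


# --------------------------------------------------------------------------
# Bilayer trajectory


@dataclass(frozen=True)
class BilayerSpec:
    """Study conditions for the synthetic bilayer.

    Defaults mirror the published simulations: 72 lipids in two leaflets
    with sodium counter-ions, lateral box ≈ 46.5 Å (area per lipid
    ≈ 60 Å²), headgroup planes ≈ ±17 Å from the midplane (D_HH ≈ 34 Å),
    and a water count giving a volume per lipid near 1020 Å³.
    """

    seed: int = 0
    n_lipid: int = 72
    n_water: int = 3258
    n_frames: int = 10
    box_xy: float = 46.5
    box_z: float = 80.0
    box_sigma: float = 0.3          # lateral box fluctuation, Å
    n_chain_carbons: int = 8
    head_offset: float = 17.0       # headgroup |z − midplane|, Å
    target_scd: dict[int, float] | None = None   # carbon → S_CD
    efield: Callable[[np.ndarray], np.ndarray] | None = None  # E*(z), e/Å²
    with_ions: bool = True
    lateral_jitter: float = 0.8


def _default_scd(n_carbons: int) -> dict[int, float]:
    # plateau ≈ −0.20 near the glycerol, decaying toward the chain end
    return {
        c: -0.20 + 0.15 * (c - 2) / max(n_carbons - 3, 1)
        for c in range(2, n_carbons + 1)
    }


def _sample_ch_direction(rng: np.random.Generator, s_target: float) -> np.ndarray:
    """Unit vector whose ⟨(3cos²θ−1)/2⟩ equals ``s_target`` exactly in
    expectation: a mixture of aligned/in-plane and isotropic draws."""
    if s_target >= 0:
        if rng.random() < s_target:
            return np.array([0.0, 0.0, 1.0])
    else:
        if rng.random() < min(-2.0 * s_target, 1.0):
            a = rng.uniform(0, 2 * math.pi)
            return np.array([math.cos(a), math.sin(a), 0.0])
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_bilayer_traj(
    spec: BilayerSpec,
) -> tuple[list[TrajectoryFrame], BilayerComposition]:
    """Generate a pseudo-lipid bilayer trajectory plus its composition."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_lipid % 2:
        raise ValueError("n_lipid must be even")
    per_leaflet = spec.n_lipid // 2
    grid_n = math.ceil(math.sqrt(per_leaflet))
    spacing = spec.box_xy / grid_n
    if spacing < 4.0:
        raise ValueError("box overfilled: lipid spacing below 4 Å")
    scd = spec.target_scd or _default_scd(spec.n_chain_carbons)

    # ---- static composition ------------------------------------------------
    labels: list[str] = []
    charges: list[float] = []
    zs: list[int] = []
    alphas: list[float] = []
    ch_pairs: dict[int, list[tuple[int, int]]] = {c: [] for c in scd}
    headgroup_vectors: list[tuple[int, int]] = []
    terminal_carbons: list[int] = []

    lipid_atoms: list[dict] = []   # per lipid: indices for geometry rebuild
    idx = 0

    def add_atom(label: str, q: float, z: int, alpha: float) -> int:
        nonlocal idx
        labels.append(label)
        charges.append(q)
        zs.append(z)
        alphas.append(alpha)
        idx += 1
        return idx - 1

    for lip in range(spec.n_lipid):
        upper = lip < per_leaflet
        slot = lip % per_leaflet
        gx, gy = slot % grid_n, slot // grid_n
        entry = {"upper": upper, "gx": gx, "gy": gy, "atoms": {}}
        p = add_atom("PO4", -0.6, 15, _ELEMENT_TABLE["P"][0])
        c2 = add_atom("GLY", 0.1, 6, _ELEMENT_TABLE["C"][0])
        headgroup_vectors.append((p, c2))
        entry["atoms"]["P"] = p
        entry["atoms"]["C2"] = c2
        chain = []
        for c in range(2, spec.n_chain_carbons + 1):
            last = c == spec.n_chain_carbons
            ci = add_atom("CH3" if last else "CH2", -0.15, 6,
                          _ELEMENT_TABLE["C"][0])
            h1 = add_atom("CH3" if last else "CH2", 0.075, 1,
                          _ELEMENT_TABLE["H"][0])
            h2 = add_atom("CH3" if last else "CH2", 0.075, 1,
                          _ELEMENT_TABLE["H"][0])
            ch_pairs[c].extend([(ci, h1), (ci, h2)])
            chain.append((c, ci, h1, h2))
            if last:
                terminal_carbons.append(ci)
        entry["atoms"]["chain"] = chain
        # per-lipid net charge −1: absorb the residual on the phosphorus
        lip_q = (-0.6 + 0.1
                 + (spec.n_chain_carbons - 1) * (-0.15 + 2 * 0.075))
        charges[p] += -1.0 - lip_q
        lipid_atoms.append(entry)

    ion_indices = []
    if spec.with_ions:
        for _ in range(spec.n_lipid):
            ion_indices.append(
                add_atom("ION", 1.0, 11, _ELEMENT_TABLE["Na"][0])
            )
    water_indices = [
        add_atom("water", 0.0, 10, 1.44) for _ in range(spec.n_water)
    ]

    comp = BilayerComposition(
        n_lipid=spec.n_lipid,
        n_water=spec.n_water,
        labels=labels,
        charges=np.array(charges),
        atomic_numbers=np.array(zs),
        polarizabilities=np.array(alphas),
        ch_pairs={"sn1": ch_pairs},
        headgroup_vectors=headgroup_vectors,
        terminal_carbons=terminal_carbons,
    )

    # ---- frames ------------------------------------------------------------
    n_atoms = comp.n_atoms
    frames: list[TrajectoryFrame] = []
    mid = spec.box_z / 2.0
    chain_span = spec.head_offset - 3.0
    for _ in range(spec.n_frames):
        lxy = spec.box_xy + rng.normal(0.0, spec.box_sigma) \
            if spec.box_sigma > 0 else spec.box_xy
        box = np.array([lxy, lxy, spec.box_z])
        coords = np.zeros((n_atoms, 3))
        for entry in lipid_atoms:
            sgn = 1.0 if entry["upper"] else -1.0
            x = (entry["gx"] + 0.5) * spacing + rng.normal(0, spec.lateral_jitter)
            y = (entry["gy"] + 0.5) * spacing + rng.normal(0, spec.lateral_jitter)
            zp = mid + sgn * (spec.head_offset + rng.normal(0, 0.8))
            p, c2 = entry["atoms"]["P"], entry["atoms"]["C2"]
            coords[p] = [x, y, zp]
            # headgroup vector mostly in-plane (tilt mode near 90°)
            a = rng.uniform(0, 2 * math.pi)
            tilt = math.radians(rng.normal(90.0, 12.0))
            vec = np.array([
                math.sin(tilt) * math.cos(a),
                math.sin(tilt) * math.sin(a),
                math.cos(tilt) * sgn,
            ])
            coords[c2] = coords[p] + 2.5 * vec
            n_c = spec.n_chain_carbons
            for c, ci, h1, h2 in entry["atoms"]["chain"]:
                frac = (c - 2) / max(n_c - 2, 1)
                zc = mid + sgn * (spec.head_offset - 2.0 - frac * chain_span)
                coords[ci] = [
                    x + rng.normal(0, 0.3), y + rng.normal(0, 0.3), zc,
                ]
                for h in (h1, h2):
                    d = _sample_ch_direction(rng, scd[c])
                    coords[h] = coords[ci] + 1.09 * d
        for k, ion in enumerate(ion_indices):
            entry = lipid_atoms[k]
            coords[ion] = coords[entry["atoms"]["P"]] + rng.normal(0, 1.5, 3)
        # waters fill the slab beyond the headgroups on both sides
        wz_span = mid - spec.head_offset - 1.5
        for w in water_indices:
            side = 1.0 if rng.random() < 0.5 else -1.0
            z = mid + side * (spec.head_offset + 1.5 + rng.uniform(0, wz_span - 0.1))
            coords[w] = [rng.uniform(0, lxy), rng.uniform(0, lxy), z]
        induced = None
        if spec.efield is not None:
            ez = spec.efield(np.mod(coords[:, 2], spec.box_z))
            induced = np.zeros((n_atoms, 3))
            induced[:, 2] = comp.polarizabilities * ez
        frames.append(TrajectoryFrame(box, coords, induced))
    return frames, comp


def toy_molecule_keyfile(system: System):
    """Express a toy molecule's parameters in the key-file dialect."""
    from .io.keyfile import KeyFile, MultipoleRecord, PolarizeRecord

    kf = KeyFile()
    for i, (site, fr) in enumerate(zip(system.sites, system.frames)):
        m = system.local_multipoles[i]
        if fr.convention == "bisector":
            za, xa = fr.anchor_z
            zc = -system.sites[za].type_class
            xc = system.sites[xa].type_class
        elif fr.convention == "none":
            zc = xc = 0
        elif fr.convention == "z_only":
            zc = system.sites[fr.anchor_z].type_class
            xc = 0
        else:
            zc = system.sites[fr.anchor_z].type_class
            xc = system.sites[fr.anchor_x].type_class
        kf.multipoles.append(MultipoleRecord(
            site.type_class, zc, xc, m.charge, m.dipole.copy(),
            m.quadrupole.copy(),
        ))
        rot = set(system.topology.rotatable_bonds)
        group = [
            system.sites[j].type_class
            for j in sorted(system.topology.neighbors(i))
            if tuple(sorted((i, j))) not in rot
        ]
        kf.polarize.append(PolarizeRecord(
            site.type_class, site.polarizability, 0.39, group
        ))
    for i, j, kb, r0 in system.bonded.bonds:
        kf.bonds.append((system.sites[i].type_class,
                         system.sites[j].type_class, kb, r0))
    for i, j, k, ka, t0 in system.bonded.angles:
        kf.angles.append((system.sites[i].type_class,
                          system.sites[j].type_class,
                          system.sites[k].type_class, ka, t0))
    for i, j, k, ks in system.bonded.stretch_bends:
        kf.strbnds.append((system.sites[i].type_class,
                           system.sites[j].type_class,
                           system.sites[k].type_class, ks))
    for i, j, k, l, amps, phases in system.bonded.torsions:
        kf.torsions.append((system.sites[i].type_class,
                            system.sites[j].type_class,
                            system.sites[k].type_class,
                            system.sites[l].type_class, amps, phases))
    for cls in sorted(system.vdw.eps):
        kf.vdws.append((cls, system.vdw.rmin[cls], system.vdw.eps[cls],
                        system.vdw.reduction.get(cls)))
    return kf
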