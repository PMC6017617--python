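"""Bilayer observables from multi-frame trajectories.

Implements the standard structural and electrostatic descriptors used to
validate lipid force fields against scattering and NMR data:

* area per lipid            A_L = L_x·L_y / (n_lipid/2)
* volume per lipid          V_L = (L_x·L_y·L_z − n_w·V_w) / n_lipid
* electron density profile  slab-binned Z − q electrons per volume,
  decomposed by chemical group; the head-to-head peak distance gives the
  bilayer thickness D_HH
* deuterium order parameter S_CD = ⟨3cos²θ − 1⟩/2 per chain carbon
* headgroup tilt            distribution of the P→C2 (or P→N) vector
  angle to the outward bilayer normal
* dipole potential          E_z(z) estimated from induced dipoles via
  μ_ind,z/α, integrated to φ(z) and referenced to bulk water

The bilayer normal is +z throughout and boxes are orthorhombic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import COULOMB, VOLT_PER_KCAL_MOL_E, WATER_VOLUME

__all__ = [
    "TrajectoryFrame",
    "BilayerComposition",
    "Profile",
    "UndefinedThicknessError",
    "area_per_lipid",
    "volume_per_lipid",
    "electron_density_profile",
    "bilayer_thickness",
    "order_parameters",
    "headgroup_angle_distribution",
    "dipole_potential",
    "DipolePotentialResult",
]


class UndefinedThicknessError(ValueError):
    """Profile lacks two separated headgroup peaks."""


@dataclass
class TrajectoryFrame:
    """One frame: orthorhombic box lengths (Å), coordinates (N×3, Å) and
    optionally per-site induced dipoles (N×3, e·Å)."""

    box: np.ndarray
    coords: np.ndarray
    induced: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.induced is not None:
            self.induced = np.asarray(self.induced, dtype=float).reshape(
                self.coords.shape
            )


@dataclass
class BilayerComposition:
    """Static description of the system the trajectory samples.

    ``labels`` assigns every atom to a group ("water", "PO4", "GLY",
    "CH2", ...).  ``ch_pairs`` maps chain name → carbon position →
    (C, H) atom-index pairs pooled over lipids; ``headgroup_vectors``
    holds one (P, partner) pair per lipid (P→C2 of glycerol for PG,
    P→N for PS); ``terminal_carbons`` are the chain-end methyl carbons
    whose mean z defines the midplane.
    """

    n_lipid: int
    n_water: int
    labels: list[str]
    charges: np.ndarray
    atomic_numbers: np.ndarray
    polarizabilities: np.ndarray | None = None
    water_volume: float = WATER_VOLUME
    ch_pairs: dict[str, dict[int, list[tuple[int, int]]]] = field(
        default_factory=dict
    )
    headgroup_vectors: list[tuple[int, int]] = field(default_factory=list)
    terminal_carbons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int).ravel()
        if len(self.labels) != len(self.charges) or len(self.labels) != len(
            self.atomic_numbers
        ):
            raise ValueError("labels/charges/atomic_numbers length mismatch")
        if self.polarizabilities is not None:
            self.polarizabilities = np.asarray(
                self.polarizabilities, dtype=float
            ).ravel()
        if self.n_lipid % 2:
            raise ValueError("n_lipid must be even (two leaflets)")

    @property
    def n_atoms(self) -> int:
        return len(self.labels)


@dataclass
class Profile:
    """Uniform slab profile along z: slab centers, values, slab width."""

    z: np.ndarray
    values: np.ndarray
    width: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.z) != len(self.values):
            raise ValueError("z/values length mismatch")


def _wrap_z(z: np.ndarray, lz: float) -> np.ndarray:
    return np.mod(z, lz)


def _midplane(frame: TrajectoryFrame, comp: BilayerComposition) -> float:
    if comp.terminal_carbons:
        return float(
            _wrap_z(frame.coords[comp.terminal_carbons, 2], frame.box[2]).mean()
        )
    return float(frame.box[2] / 2.0)


# --------------------------------------------------------------------------


def area_per_lipid(
    frames: Sequence[TrajectoryFrame], comp: BilayerComposition
) -> tuple[float, float]:
    """Time mean and standard deviation of L_x·L_y/(n_lipid/2), Å²."""
    if comp.n_lipid <= 0:
        raise ValueError("n_lipid must be positive")
    vals = np.array(
        [f.box[0] * f.box[1] / (comp.n_lipid / 2.0) for f in frames]
    )
    return float(vals.mean()), float(vals.std())


def volume_per_lipid(
    frames: Sequence[TrajectoryFrame], comp: BilayerComposition
) -> tuple[float, float]:
    """Time mean and sd of (L_xL_yL_z − n_w·V_w)/n_lipid, Å³.

    The water contribution uses a fixed per-molecule volume
    (default 30.53 Å³)."""
    vals = []
    for f in frames:
        v = float(np.prod(f.box)) - comp.n_water * comp.water_volume
        if v <= 0:
            raise ValueError("water volume exceeds the box volume")
        vals.append(v / comp.n_lipid)
    arr = np.array(vals)
    return float(arr.mean()), float(arr.std())


def electron_density_profile(
    frames: Sequence[TrajectoryFrame],
    comp: BilayerComposition,
    n_slabs: int = 100,
) -> dict[str, Profile]:
    """Frame-averaged electron density (e/Å³) per group and in total.

    Each atom carries Z − q electrons (permanent monopole only; dipole
    and quadrupole contributions are not counted).  Atoms are wrapped
    into [0, L_z) and binned into half-open slabs; the group profiles sum
    to the total by construction.
    """
    electrons = comp.atomic_numbers - comp.charges
    groups = sorted(set(comp.labels))
    gidx = {g: np.array([i for i, l in enumerate(comp.labels) if l == g])
            for g in groups}
    acc = {g: np.zeros(n_slabs) for g in groups}
    width_acc = 0.0
    for f in frames:
        lz = f.box[2]
        area = f.box[0] * f.box[1]
        dz = lz / n_slabs
        width_acc += dz
        zi = np.minimum(
            (_wrap_z(f.coords[:, 2], lz) / dz).astype(int), n_slabs - 1
        )
        vol = area * dz
        for g in groups:
            idx = gidx[g]
            acc[g] += np.bincount(
                zi[idx], weights=electrons[idx], minlength=n_slabs
            ) / vol
    nf = len(frames)
    width = width_acc / nf
    centers = (np.arange(n_slabs) + 0.5) * width
    out = {g: Profile(centers, acc[g] / nf, width) for g in groups}
    out["total"] = Profile(
        centers, sum(acc[g] for g in groups) / nf, width
    )
    return out


def _refine_peak(z: np.ndarray, v: np.ndarray, k: int) -> float:
    """Parabolic sub-bin refinement of a local maximum at index k."""
    if k == 0 or k == len(v) - 1:
        return float(z[k])
    denom = v[k - 1] - 2 * v[k] + v[k + 1]
    if abs(denom) < 1e-300:
        return float(z[k])
    shift = 0.5 * (v[k - 1] - v[k + 1]) / denom
    return float(z[k] + np.clip(shift, -1, 1) * (z[1] - z[0]))


def bilayer_thickness(edp: Profile, midplane: float | None = None) -> float:
    """Head-to-head distance D_HH: the separation of the two density
    peaks on opposite sides of the midplane, with parabolic sub-bin
    refinement.  Raises :class:`UndefinedThicknessError` when one side
    has no interior local maximum."""
    v = edp.values
    z = edp.z
    mid = float(z.mean()) if midplane is None else midplane
    local_max = [
        k for k in range(1, len(v) - 1)
        if v[k] >= v[k - 1] and v[k] >= v[k + 1] and (v[k] > v[k - 1] or v[k] > v[k + 1])
    ]
    lower = [k for k in local_max if z[k] < mid]
    upper = [k for k in local_max if z[k] >= mid]
    if not lower or not upper:
        raise UndefinedThicknessError(
            "need one density peak on each side of the midplane"
        )
    kl = max(lower, key=lambda k: v[k])
    ku = max(upper, key=lambda k: v[k])
    return abs(_refine_peak(z, v, ku) - _refine_peak(z, v, kl))


def order_parameters(
    frames: Sequence[TrajectoryFrame],
    comp: BilayerComposition,
) -> dict[str, dict[int, float]]:
    """Deuterium order parameter S_CD = ⟨3cos²θ − 1⟩/2 per chain carbon,
    θ measured between each C–H (C–D proxy) bond and the bilayer normal
    (+z), averaged over equivalent hydrogens, lipids and frames.

    S_CD = 1 for bonds along the normal, −1/2 in the membrane plane, and
    0 for isotropic orientations (or the magic angle ≈ 54.7°).
    """
    out: dict[str, dict[int, float]] = {}
    for chain, carbons in comp.ch_pairs.items():
        out[chain] = {}
        for carbon, pairs in sorted(carbons.items()):
            if not pairs:
                continue
            vals = []
            for f in frames:
                ci = np.array([p[0] for p in pairs])
                hi = np.array([p[1] for p in pairs])
                v = f.coords[hi] - f.coords[ci]
                c2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
                vals.append(0.5 * (3.0 * c2 - 1.0))
            out[chain][carbon] = float(np.concatenate(vals).mean())
    return out


def order_parameter_of_vectors(vectors: np.ndarray) -> float:
    """S_CD of an explicit bundle of bond vectors (N×3) against +z."""
    v = np.asarray(vectors, dtype=float).reshape(-1, 3)
    c2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
    return float(np.mean(0.5 * (3.0 * c2 - 1.0)))


def headgroup_angle_distribution(
    frames: Sequence[TrajectoryFrame],
    comp: BilayerComposition,
    bin_deg: float = 5.0,
) -> tuple[Profile, float]:
    """Probability density of the headgroup-vector tilt over [0°, 180°].

    The tilt is the angle between the per-lipid headgroup vector and the
    *outward* bilayer normal (+z in the upper leaflet, −z in the lower,
    split at the terminal-methyl midplane).  The density integrates to 1
    over degrees; the modal angle is returned alongside.
    """
    if not comp.headgroup_vectors:
        raise ValueError("composition defines no headgroup vectors")
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    counts = np.zeros(len(edges) - 1)
    for f in frames:
        mid = _midplane(f, comp)
        lz = f.box[2]
        for p_idx, q_idx in comp.headgroup_vectors:
            v = f.coords[q_idx] - f.coords[p_idx]
            n = np.linalg.norm(v)
            if n < 1e-12:
                raise ValueError("zero-length headgroup vector")
            upper = _wrap_z(np.array([f.coords[p_idx, 2]]), lz)[0] >= mid
            cosang = v[2] / n if upper else -v[2] / n
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            k = min(int(ang / bin_deg), len(counts) - 1)
            counts[k] += 1
    total = counts.sum()
    density = counts / (total * bin_deg)
    centers = edges[:-1] + bin_deg / 2.0
    mode = float(centers[int(np.argmax(counts))])
    return Profile(centers, density, bin_deg), mode


@dataclass
class DipolePotentialResult:
    ez: Profile                 # kcal/(mol·e·Å)
    phi: Profile                # Volt
    delta_phi: float            # Volt, φ(bilayer center) − φ(water plateau)
    interpolated_slabs: list[int]


def dipole_potential(
    frames: Sequence[TrajectoryFrame],
    comp: BilayerComposition,
    n_slabs: int = 100,
    water_fraction_plateau: float = 0.9,
) -> DipolePotentialResult:
    """Membrane dipole potential profile from induced dipoles.

    Per slab, the mean electric field along the normal is estimated from
    the induced-dipole definition inverted per atom, E_z ≈ ⟨μ_ind,z/α⟩
    over the polarizable atoms in the slab (α = 0 atoms are excluded),
    converted to kcal/(mol·e·Å).  The potential φ(z) = ∫₀^z E_z dz is
    accumulated by the trapezoid rule from the box edge (bulk water) and
    reported in Volts; Δφ is φ at the bilayer center minus the mean φ
    over the water plateau (slabs dominated by water atoms).  Slabs that
    never contain an eligible atom are linearly interpolated from their
    neighbours and flagged.
    """
    if comp.polarizabilities is None:
        raise ValueError("composition lacks polarizabilities")
    alpha = comp.polarizabilities
    eligible = alpha > 0
    sums = np.zeros(n_slabs)
    counts = np.zeros(n_slabs)
    water_counts = np.zeros(n_slabs)
    all_counts = np.zeros(n_slabs)
    lz_mean = 0.0
    is_water = np.array([l == "water" for l in comp.labels])
    for f in frames:
        if f.induced is None:
            raise ValueError("frame lacks induced dipoles")
        lz = f.box[2]
        lz_mean += lz
        dz = lz / n_slabs
        zi = np.minimum(
            (_wrap_z(f.coords[:, 2], lz) / dz).astype(int), n_slabs - 1
        )
        ratio = np.zeros(len(alpha))
        ratio[eligible] = f.induced[eligible, 2] / alpha[eligible]
        sums += np.bincount(zi[eligible], weights=ratio[eligible],
                            minlength=n_slabs)
        counts += np.bincount(zi[eligible], minlength=n_slabs)
        water_counts += np.bincount(zi[is_water], minlength=n_slabs)
        all_counts += np.bincount(zi, minlength=n_slabs)
    lz_mean /= len(frames)
    width = lz_mean / n_slabs
    centers = (np.arange(n_slabs) + 0.5) * width

    ez = np.zeros(n_slabs)
    nonzero = counts > 0
    ez[nonzero] = sums[nonzero] / counts[nonzero]
    interpolated = [int(k) for k in np.nonzero(~nonzero)[0]]
    if interpolated and nonzero.any():
        ez[~nonzero] = np.interp(
            centers[~nonzero], centers[nonzero], ez[nonzero]
        )
    ez_units = ez * COULOMB                       # e/Å² → kcal/(mol·e·Å)

    phi_kcal = np.concatenate(
        [[0.0], np.cumsum(0.5 * (ez_units[1:] + ez_units[:-1]) * width)]
    )
    phi_v = phi_kcal * VOLT_PER_KCAL_MOL_E

    # Reference: water-dominated slabs; fall back to the outer 5% of slabs.
    with np.errstate(invalid="ignore", divide="ignore"):
        wfrac = np.where(all_counts > 0, water_counts / np.maximum(all_counts, 1), 0.0)
    plateau = wfrac >= water_fraction_plateau
    if not plateau.any():
        edge = max(1, n_slabs // 20)
        plateau = np.zeros(n_slabs, dtype=bool)
        plateau[:edge] = plateau[-edge:] = True
    mid = _midplane(frames[0], comp)
    k_mid = min(int(mid / width), n_slabs - 1)
    delta = float(phi_v[k_mid] - phi_v[plateau].mean())
    return DipolePotentialResult(
        Profile(centers, ez_units, width),
        Profile(centers, phi_v, width),
        delta,
        interpolated,
    )
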