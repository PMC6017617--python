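"""Potential-energy terms for a fixed configuration.

The total energy decomposes as

    U = U_bond + U_angle + U_bθ + U_oop + U_torsion
        + U_vdW + U_ele_perm + U_ele_ind

with anharmonic bonded terms (quartic Morse-expansion bonds, sextic
angles, stretch-bend coupling, Wilson–Decius–Cross out-of-plane bending,
six-term Fourier torsions), Halgren's buffered 14-7 repulsion-dispersion
with hydrogen reduction factors, permanent atomic-multipole
electrostatics through quadrupole–quadrupole order, and self-consistent
Thole-damped induced dipoles.

All electrostatics is direct-space pairwise (minimum image when a box is
supplied); there is no Ewald/PME here and no gradients — the module
evaluates energies of given configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import DEFAULT_CONFIG, ForceFieldConfig
from .constants import DEBYE_PER_EA
from .mpole import MultipoleSet, PolarizableSite
from .topology import Topology

__all__ = [
    "BondedParams",
    "VdwParams",
    "InducedDipoles",
    "EnergyBreakdown",
    "System",
    "SingularGeometryError",
    "UndefinedGeometryError",
    "InductionDivergenceError",
    "bonded_energy",
    "vdw_energy",
    "permanent_electrostatics",
    "permanent_field",
    "induce_dipoles",
    "polarization_energy",
    "total_energy",
]


class SingularGeometryError(ValueError):
    """Coincident interaction sites (r = 0)."""


class UndefinedGeometryError(ValueError):
    """Internal coordinate undefined (e.g. angle at exactly 0° or 180°)."""


class InductionDivergenceError(RuntimeError):
    """SCF induction failed to converge within the iteration budget."""

    def __init__(self, iterations: int, last_change_debye: float):
        self.iterations = iterations
        self.last_change_debye = last_change_debye
        super().__init__(
            f"induced dipoles not converged after {iterations} iterations "
            f"(last max change {last_change_debye:.3e} D)"
        )


# --------------------------------------------------------------------------
# Parameter containers


@dataclass
class BondedParams:
    """Bonded parameter lists, indexed by site.

    bonds: (i, j, k_b kcal/mol/Å², r0 Å)
    angles: (i, j, k, k_θ kcal/mol/rad², θ0 deg) with j the vertex
    stretch_bends: (i, j, k, k_sb kcal/mol/Å/rad) referencing an angle at j
    oops: (center, a, b, d, k_oop kcal/mol/rad²) — χ is the angle of the
        center→d bond out of the a-center-b plane
    torsions: (i, j, k, l, amplitudes (V1..V6) kcal/mol, phases (γ1..γ6) deg)
    """

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    stretch_bends: list[tuple[int, int, int, float]] = field(default_factory=list)
    oops: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    torsions: list[
        tuple[int, int, int, int, tuple[float, ...], tuple[float, ...]]
    ] = field(default_factory=list)


@dataclass
class VdwParams:
    """Per-class buffered 14-7 parameters.

    ``reduction`` moves a hydrogen's interaction site toward its bonded
    heavy atom: site' = heavy + f·(H − heavy), f ∈ (0, 1].
    """

    eps: dict[int, float] = field(default_factory=dict)      # kcal/mol
    rmin: dict[int, float] = field(default_factory=dict)     # Å
    reduction: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, e in self.eps.items():
            if e < 0:
                raise ValueError(f"eps < 0 for class {c}")
        for c, r in self.rmin.items():
            if r <= 0:
                raise ValueError(f"rmin <= 0 for class {c}")


@dataclass
class InducedDipoles:
    """Converged (or not) per-site induced dipoles, e·Å."""

    mu: np.ndarray                 # (N, 3)
    converged: bool
    iterations: int
    final_change_debye: float
    perm_field: np.ndarray | None = None  # field of permanent multipoles, e/Å²
    history: list[float] = field(default_factory=list)  # per-iteration max Δμ, D


@dataclass
class EnergyBreakdown:
    U_bond: float = 0.0
    U_angle: float = 0.0
    U_strbend: float = 0.0
    U_oop: float = 0.0
    U_torsion: float = 0.0
    U_vdw: float = 0.0
    U_ele_perm: float = 0.0
    U_ele_ind: float = 0.0

    @property
    def U_total(self) -> float:
        return (
            self.U_bond + self.U_angle + self.U_strbend + self.U_oop
            + self.U_torsion + self.U_vdw + self.U_ele_perm + self.U_ele_ind
        )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in (
            "U_bond", "U_angle", "U_strbend", "U_oop", "U_torsion",
            "U_vdw", "U_ele_perm", "U_ele_ind")}
        d["U_total"] = self.U_total
        return d


# --------------------------------------------------------------------------
# Geometry helpers


def _min_image(s: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return s
    return s - box * np.round(s / box)


def _angle_deg(a: np.ndarray, j: np.ndarray, k: np.ndarray) -> float:
    u, v = a - j, k - j
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise UndefinedGeometryError("zero-length bond in angle")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    if abs(c) >= 1.0 - 1e-12:
        raise UndefinedGeometryError("angle at exactly 0° or 180°")
    return math.degrees(math.acos(c))


def dihedral_deg(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral angle in degrees, IUPAC convention."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = n1 @ n2, m1 @ n2
    return math.degrees(math.atan2(y, x))


# --------------------------------------------------------------------------
# Bonded terms


def bonded_energy(
    coords: np.ndarray,
    params: BondedParams,
    config: ForceFieldConfig = DEFAULT_CONFIG,
) -> EnergyBreakdown:
    """Evaluate every bonded term of the potential.

    Bond:     k·Δ²(1 + c₃Δ + c₄Δ²), Δ = r − r0 in Å.
    Angle/OOP: k·Δθ_rad²·(1 + d₃Δθ + d₄Δθ² + d₅Δθ³ + d₆Δθ⁴) with the
               quadratic in radians and the correction polynomial in
               degrees (the convention under which the standard
               coefficients are quoted).
    Str-bend: k_sb(Δr_ij + Δr_kj)·Δθ_rad.
    Torsion:  Σ_n (V_n/2)(1 + cos(nφ − γ_n)), n = 1..6.
    """
    coords = np.asarray(coords, dtype=float)
    out = EnergyBreakdown()
    c3, c4 = config.bond_cubic, config.bond_quartic
    d3, d4 = config.angle_cubic, config.angle_quartic
    d5, d6 = config.angle_pentic, config.angle_sextic

    bond_delta: dict[tuple[int, int], float] = {}
    for i, j, kb, r0 in params.bonds:
        r = float(np.linalg.norm(coords[j] - coords[i]))
        dlt = r - r0
        bond_delta[(i, j)] = bond_delta[(j, i)] = dlt
        out.U_bond += kb * dlt**2 * (1.0 + c3 * dlt + c4 * dlt**2)

    def _poly(k: float, dtheta_deg: float) -> float:
        dt_rad = math.radians(dtheta_deg)
        return k * dt_rad**2 * (
            1.0 + d3 * dtheta_deg + d4 * dtheta_deg**2
            + d5 * dtheta_deg**3 + d6 * dtheta_deg**4
        )

    angle_delta: dict[tuple[int, int, int], float] = {}
    for i, j, k, kt, t0 in params.angles:
        theta = _angle_deg(coords[i], coords[j], coords[k])
        dt = theta - t0
        angle_delta[(i, j, k)] = angle_delta[(k, j, i)] = dt
        out.U_angle += _poly(kt, dt)

    for i, j, k, ksb in params.stretch_bends:
        if (i, j, k) not in angle_delta:
            raise KeyError(f"stretch-bend ({i},{j},{k}) has no matching angle")
        dr1 = bond_delta.get((i, j))
        dr2 = bond_delta.get((k, j))
        if dr1 is None or dr2 is None:
            raise KeyError(f"stretch-bend ({i},{j},{k}) misses a bond parameter")
        out.U_strbend += ksb * (dr1 + dr2) * math.radians(angle_delta[(i, j, k)])

    for c, a, b, d, koop in params.oops:
        n = np.cross(coords[a] - coords[c], coords[b] - coords[c])
        nn = np.linalg.norm(n)
        u = coords[d] - coords[c]
        nu = np.linalg.norm(u)
        if nn < 1e-12 or nu < 1e-12:
            raise UndefinedGeometryError("degenerate out-of-plane geometry")
        sin_chi = np.clip(n @ u / (nn * nu), -1.0, 1.0)
        chi_deg = math.degrees(math.asin(abs(sin_chi)))
        out.U_oop += _poly(koop, chi_deg)

    for i, j, k, l, amps, phases in params.torsions:
        phi = dihedral_deg(coords[i], coords[j], coords[k], coords[l])
        for n, (v, g) in enumerate(zip(amps, phases), start=1):
            out.U_torsion += 0.5 * v * (1.0 + math.cos(math.radians(n * phi - g)))
    return out


# --------------------------------------------------------------------------
# Buffered 14-7 van der Waals


def buffered_14_7(r: float, eps: float, rmin: float,
                  delta: float = 0.07, gamma: float = 0.12) -> float:
    """Halgren's buffered 14-7 pair energy, kcal/mol.  U(r_min) = −ε."""
    if r <= 0:
        raise SingularGeometryError("vdW at r = 0")
    rho = r / rmin
    return eps * ((1 + delta) / (rho + delta)) ** 7 * (
        (1 + gamma) / (rho**7 + gamma) - 2.0
    )


def _combine_vdw(e1: float, e2: float, r1: float, r2: float) -> tuple[float, float]:
    # Cubic-mean r_min, HHG epsilon (the AMOEBA combining rules).
    rmin = (r1**3 + r2**3) / (r1**2 + r2**2)
    if e1 == 0.0 or e2 == 0.0:
        return 0.0, rmin
    eps = 4.0 * e1 * e2 / (math.sqrt(e1) + math.sqrt(e2)) ** 2
    return eps, rmin


def vdw_energy(
    coords: np.ndarray,
    sites: Sequence[PolarizableSite],
    params: VdwParams,
    topology: Topology,
    config: ForceFieldConfig = DEFAULT_CONFIG,
    box: np.ndarray | None = None,
) -> float:
    """Pairwise buffered 14-7 energy with connectivity scaling and
    hydrogen reduction.

    Hydrogen interaction centers are displaced toward their bonded heavy
    atom by the per-class reduction factor before any distance is taken.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(sites)
    if n == 0:
        return 0.0
    pos = coords.copy()
    for s in sites:
        red = params.reduction.get(s.type_class)
        if red is None or s.atomic_number != 1:
            continue
        nb = topology.neighbors(s.index)
        if len(nb) != 1:
            raise ValueError(f"hydrogen {s.index} must have exactly one neighbor")
        heavy = next(iter(nb))
        pos[s.index] = coords[heavy] + red * (coords[s.index] - coords[heavy])

    scale = topology.pair_scale_matrix(config.vdw_scale)
    total = 0.0
    for i in range(n):
        ci = sites[i].type_class
        if ci not in params.eps:
            continue
        for j in range(i + 1, n):
            if scale[i, j] == 0.0:
                continue
            cj = sites[j].type_class
            if cj not in params.eps:
                continue
            eps, rmin = _combine_vdw(
                params.eps[ci], params.eps[cj], params.rmin[ci], params.rmin[cj]
            )
            s = _min_image(pos[j] - pos[i], box)
            r = float(np.linalg.norm(s))
            total += scale[i, j] * buffered_14_7(
                r, eps, rmin, config.vdw_delta, config.vdw_gamma
            )
    return total


# --------------------------------------------------------------------------
# Permanent multipole electrostatics
#
# With s = r_i − r_j, the potential of site j's multipole at site i is
#   φ = q/r + (μ·s)/r³ + (3/2)(sᵀQs)/r⁵
# and the pair energy is U = q_i φ + μ_i·∇φ + (1/2) Q_i : ∇∇φ, all
# gradients with respect to r_i.  Q is the traceless second moment.


def _pair_potential_grad_hess(
    qj: float, muj: np.ndarray, Qj: np.ndarray, s: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    r2 = float(s @ s)
    if r2 < 1e-20:
        raise SingularGeometryError("coincident multipole sites")
    r = math.sqrt(r2)
    r3, r5, r7, r9 = r * r2, r2**2 * r, r2**3 * r, r2**4 * r
    mus = float(muj @ s)
    Qs = Qj @ s
    sQs = float(s @ Qs)
    I = np.eye(3)

    phi = qj / r + mus / r3 + 1.5 * sQs / r5

    grad = (
        -qj * s / r3
        - 3.0 * mus * s / r5 + muj / r3
        - 7.5 * sQs * s / r7 + 3.0 * Qs / r5
    )

    ss = np.outer(s, s)
    hess = (
        qj * (3.0 * ss / r5 - I / r3)
        + 15.0 * mus * ss / r7
        - 3.0 * (mus * I + np.outer(muj, s) + np.outer(s, muj)) / r5
        + 52.5 * sQs * ss / r9
        - 15.0 * (np.outer(Qs, s) + np.outer(s, Qs)) / r7
        - 7.5 * sQs * I / r7
        + 3.0 * Qj / r5
    )
    return phi, grad, hess


def multipole_pair_energy(
    mi, mj, s: np.ndarray, coulomb: float
) -> float:
    """Interaction energy of two global-frame multipoles separated by
    s = r_i − r_j, kcal/mol (before any connectivity scaling)."""
    phi, grad, hess = _pair_potential_grad_hess(
        mj.charge, mj.dipole, mj.quadrupole, s
    )
    u = (
        mi.charge * phi
        + float(mi.dipole @ grad)
        + 0.5 * float(np.tensordot(mi.quadrupole, hess))
    )
    return coulomb * u


def permanent_electrostatics(
    sites: Sequence[PolarizableSite],
    mpoles: MultipoleSet,
    topology: Topology,
    config: ForceFieldConfig = DEFAULT_CONFIG,
    box: np.ndarray | None = None,
) -> float:
    """Permanent multipole–multipole energy over unique pairs, kcal/mol,
    with 1-2/1-3/1-4/1-5 connectivity scaling.  Direct sum, minimum
    image when ``box`` is given."""
    if mpoles.frame_tag != "global":
        raise ValueError("permanent_electrostatics needs a global-frame set")
    n = len(sites)
    if n < 2:
        return 0.0
    coords = np.array([s.position for s in sites])
    scale = topology.pair_scale_matrix(config.mpole_scale)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if scale[i, j] == 0.0:
                continue
            s = _min_image(coords[i] - coords[j], box)
            total += scale[i, j] * multipole_pair_energy(
                mpoles[i], mpoles[j], s, config.coulomb
            )
    return total


# --------------------------------------------------------------------------
# Thole-damped induction


def _thole_lambdas(r: float, alpha_i: float, alpha_j: float,
                   a: float) -> tuple[float, float, float]:
    """Damping factors (λ3, λ5, λ7) from the smeared charge density
    ρ ∝ exp(−a·u³), u = r/(α_iα_j)^{1/6}.  Undamped when either α = 0."""
    if alpha_i <= 0.0 or alpha_j <= 0.0:
        return 1.0, 1.0, 1.0
    u = r / (alpha_i * alpha_j) ** (1.0 / 6.0)
    v = a * u**3
    if v > 50.0:
        return 1.0, 1.0, 1.0
    ev = math.exp(-v)
    l3 = 1.0 - ev
    l5 = 1.0 - (1.0 + v) * ev
    l7 = 1.0 - (1.0 + v + 0.6 * v * v) * ev
    return l3, l5, l7


def permanent_field(
    sites: Sequence[PolarizableSite],
    mpoles: MultipoleSet,
    topology: Topology,
    config: ForceFieldConfig = DEFAULT_CONFIG,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Thole-damped field (e/Å²) of the permanent multipoles at every
    site, excluding sources in the same polarization group."""
    if mpoles.frame_tag != "global":
        raise ValueError("permanent_field needs a global-frame set")
    n = len(sites)
    coords = np.array([s.position for s in sites]).reshape(n, 3)
    mask = topology.group_mask()
    E = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j or mask[i, j]:
                continue
            s = _min_image(coords[i] - coords[j], box)
            r = float(np.linalg.norm(s))
            if r < 1e-12:
                raise SingularGeometryError("coincident sites in field sum")
            l3, l5, l7 = _thole_lambdas(
                r, sites[i].polarizability, sites[j].polarizability,
                config.thole_a,
            )
            m = mpoles[j]
            r3, r5, r7 = r**3, r**5, r**7
            mus = float(m.dipole @ s)
            Qs = m.quadrupole @ s
            sQs = float(s @ Qs)
            E[i] += (
                m.charge * l3 * s / r3
                + 3.0 * l5 * mus * s / r5 - l3 * m.dipole / r3
                + 7.5 * l7 * sQs * s / r7 - 3.0 * l5 * Qs / r5
            )
    return E


def _dipole_field_matrix(
    sites: Sequence[PolarizableSite],
    config: ForceFieldConfig,
    box: np.ndarray | None,
) -> np.ndarray:
    """(N,N,3,3) Thole-damped dipole interaction tensor: field at i from a
    unit dipole at j (zero block on the diagonal)."""
    n = len(sites)
    coords = np.array([s.position for s in sites]).reshape(n, 3)
    T = np.zeros((n, n, 3, 3))
    I = np.eye(3)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = _min_image(coords[i] - coords[j], box)
            r = float(np.linalg.norm(s))
            if r < 1e-12:
                raise SingularGeometryError("coincident polarizable sites")
            l3, l5, _ = _thole_lambdas(
                r, sites[i].polarizability, sites[j].polarizability,
                config.thole_a,
            )
            T[i, j] = 3.0 * l5 * np.outer(s, s) / r**5 - l3 * I / r**3
    return T


def induce_dipoles(
    sites: Sequence[PolarizableSite],
    mpoles: MultipoleSet,
    topology: Topology,
    config: ForceFieldConfig = DEFAULT_CONFIG,
    box: np.ndarray | None = None,
) -> InducedDipoles:
    """Solve μ_i = α_i (E_i^perm + Σ_j T_ij μ_j) self-consistently.

    Jacobi iteration with successive over-relaxation; convergence is the
    maximum per-site dipole change in Debye falling below the configured
    tolerance (default 1e-5 D).  Raises
    :class:`InductionDivergenceError` past the iteration budget.
    """
    n = len(sites)
    alphas = np.array([s.polarizability for s in sites])
    if n == 0:
        return InducedDipoles(np.zeros((0, 3)), True, 0, 0.0, np.zeros((0, 3)))
    E0 = permanent_field(sites, mpoles, topology, config, box)
    if not np.any(alphas > 0) or not np.any(E0):
        return InducedDipoles(np.zeros((n, 3)), True, 1, 0.0, E0)
    T = _dipole_field_matrix(sites, config, box)
    mu = alphas[:, None] * E0
    omega = config.scf_omega
    tol_ea = config.scf_tolerance_debye / DEBYE_PER_EA
    history: list[float] = []
    for it in range(1, config.scf_max_iterations + 1):
        field = E0 + np.einsum("ijab,jb->ia", T, mu)
        mu_new = (1.0 - omega) * mu + omega * alphas[:, None] * field
        change = float(np.abs(mu_new - mu).max())
        history.append(change * DEBYE_PER_EA)
        mu = mu_new
        if change < tol_ea:
            return InducedDipoles(
                mu, True, it, change * DEBYE_PER_EA, E0, history
            )
    raise InductionDivergenceError(
        config.scf_max_iterations, change * DEBYE_PER_EA
    )


def polarization_energy(
    induced: InducedDipoles,
    perm_field: np.ndarray | None = None,
    coulomb: float = DEFAULT_CONFIG.coulomb,
) -> float:
    """Polarization energy U = −(1/2) Σ_i μ_i·E_i^perm, kcal/mol.

    Non-positive whenever all polarizabilities are non-negative (the
    induced dipoles minimize the polarization functional).
    """
    if not induced.converged:
        raise ValueError("refusing to evaluate an unconverged induction result")
    E = induced.perm_field if perm_field is None else perm_field
    if E is None:
        raise ValueError("permanent field not available")
    return -0.5 * coulomb * float(np.sum(induced.mu * E))


# --------------------------------------------------------------------------
# Whole-system evaluation


@dataclass
class System:
    """Everything needed to evaluate the full potential once."""

    sites: list[PolarizableSite]
    topology: Topology
    local_multipoles: MultipoleSet
    frames: list
    bonded: BondedParams = field(default_factory=BondedParams)
    vdw: VdwParams = field(default_factory=VdwParams)
    box: np.ndarray | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([s.position for s in self.sites]).reshape(-1, 3)


def total_energy(
    system: System, config: ForceFieldConfig = DEFAULT_CONFIG
) -> EnergyBreakdown:
    """Evaluate every term of the potential for one configuration."""
    from .mpole import rotate_to_global

    if not system.sites:
        return EnergyBreakdown()
    coords = system.coords
    out = bonded_energy(coords, system.bonded, config)
    out.U_vdw = vdw_energy(
        coords, system.sites, system.vdw, system.topology, config, system.box
    )
    gset = rotate_to_global(system.local_multipoles, system.frames, coords)
    out.U_ele_perm = permanent_electrostatics(
        system.sites, gset, system.topology, config, system.box
    )
    induced = induce_dipoles(
        system.sites, gset, system.topology, config, system.box
    )
    out.U_ele_ind = polarization_energy(induced, coulomb=config.coulomb)
    return out
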