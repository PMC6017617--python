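"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's interaction-tensor code paths:

* a multipole is replaced by a finite point-charge cluster of scale h
  whose monopole/dipole/quadrupole moments match exactly, and energies /
  potentials are evaluated as plain Coulomb sums — in 60-digit decimal
  arithmetic, because the cluster charges grow like 1/h² and the sums
  cancel catastrophically in double precision;
* the induced-dipole fixed point is solved directly as a dense 3N×3N
  linear system.
"""

from __future__ import annotations

from decimal import Decimal, getcontext

import numpy as np

getcontext().prec = 60

COULOMB_STR = "332.0637"
_QCOMPS = [(0, 0), (1, 1), (0, 1), (0, 2), (1, 2)]


def _D(x) -> Decimal:
    return Decimal(float(x))


def point_charge_cluster(
    charge: float,
    dipole: np.ndarray,
    quadrupole: np.ndarray,
    h: float,
    rng: np.random.Generator,
    n_points: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Charges at displacements of scale h reproducing q, μ and the
    traceless second moment Q = Σc(dd − d²I/3) exactly.

    The moment system is solved at unit scale (so its conditioning does
    not degrade as h → 0) and rescaled analytically.
    """
    u = rng.normal(size=(n_points, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    u *= rng.uniform(0.3, 1.0, n_points)[:, None]
    A = np.zeros((9, n_points))
    A[0] = 1.0
    A[1:4] = u.T
    quad = u[:, :, None] * u[:, None, :] - (
        np.sum(u * u, axis=1)[:, None, None] / 3.0
    ) * np.eye(3)
    for k, (a, b) in enumerate(_QCOMPS):
        A[4 + k] = quad[:, a, b]
    b = np.concatenate([
        [charge],
        np.asarray(dipole, dtype=float) / h,
        [np.asarray(quadrupole, dtype=float)[a, b] / h**2 for a, b in _QCOMPS],
    ])
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    return h * u, c


def coulomb_sum_decimal(
    pos_i: np.ndarray, q_i: np.ndarray,
    pos_j: np.ndarray, q_j: np.ndarray,
) -> float:
    """Pairwise Coulomb energy between two charge sets, kcal/mol,
    accumulated in 60-digit decimals."""
    total = Decimal(0)
    pi = [[_D(x) for x in p] for p in np.atleast_2d(pos_i)]
    pj = [[_D(x) for x in p] for p in np.atleast_2d(pos_j)]
    ci = [_D(x) for x in np.atleast_1d(q_i)]
    cj = [_D(x) for x in np.atleast_1d(q_j)]
    for a in range(len(pi)):
        for b in range(len(pj)):
            r2 = sum((pi[a][k] - pj[b][k]) ** 2 for k in range(3))
            total += ci[a] * cj[b] / r2.sqrt()
    return float(Decimal(COULOMB_STR) * total)


def potential_sum_decimal(
    pos: np.ndarray, q: np.ndarray, point: np.ndarray
) -> float:
    """Coulomb potential of a charge set at one point, kcal/mol/e."""
    total = Decimal(0)
    P = [_D(x) for x in point]
    for p, c in zip(np.atleast_2d(pos), np.atleast_1d(q)):
        r2 = sum((_D(p[k]) - P[k]) ** 2 for k in range(3))
        total += _D(c) / r2.sqrt()
    return float(Decimal(COULOMB_STR) * total)


def pairwise_multipole_energy_oracle(
    coords: np.ndarray,
    mpoles,
    scale: np.ndarray,
    h: float,
    seed: int = 7,
) -> float:
    """Permanent electrostatic energy of a whole multipole set by
    cluster expansion: every site becomes a point-charge cluster, every
    scaled unique pair is summed exactly."""
    rng = np.random.default_rng(seed)
    clusters = []
    for i, m in enumerate(mpoles.multipoles):
        d, c = point_charge_cluster(m.charge, m.dipole, m.quadrupole, h, rng)
        clusters.append((coords[i] + d, c))
    total = 0.0
    n = len(clusters)
    for i in range(n):
        for j in range(i + 1, n):
            if scale[i, j] == 0.0:
                continue
            total += scale[i, j] * coulomb_sum_decimal(
                clusters[i][0], clusters[i][1],
                clusters[j][0], clusters[j][1],
            )
    return total


def esp_oracle(
    coords: np.ndarray, mpoles, points: np.ndarray, h: float, seed: int = 7
) -> np.ndarray:
    """ESP of a multipole set by cluster expansion, kcal/mol/e."""
    rng = np.random.default_rng(seed)
    clusters = []
    for i, m in enumerate(mpoles.multipoles):
        d, c = point_charge_cluster(m.charge, m.dipole, m.quadrupole, h, rng)
        clusters.append((coords[i] + d, c))
    out = np.zeros(len(points))
    for k, p in enumerate(np.atleast_2d(points)):
        out[k] = sum(
            potential_sum_decimal(pos, q, p) for pos, q in clusters
        )
    return out


def dense_induction_solve(
    positions: np.ndarray,
    alphas: np.ndarray,
    perm_field: np.ndarray,
    thole_a: float,
) -> np.ndarray:
    """Induced dipoles from the exact 3N×3N linear response
    (I/α − T)μ = E_perm with Thole-damped dipole coupling."""
    n = len(alphas)
    A = np.zeros((3 * n, 3 * n))
    rhs = np.asarray(perm_field, dtype=float).reshape(3 * n)
    for i in range(n):
        if alphas[i] > 0:
            A[3 * i:3 * i + 3, 3 * i:3 * i + 3] = np.eye(3) / alphas[i]
        else:
            A[3 * i:3 * i + 3, 3 * i:3 * i + 3] = np.eye(3) * 1e30
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = positions[i] - positions[j]
            r = np.linalg.norm(s)
            if alphas[i] > 0 and alphas[j] > 0:
                u = r / (alphas[i] * alphas[j]) ** (1.0 / 6.0)
                v = thole_a * u**3
                ev = np.exp(-v) if v < 50 else 0.0
                l3 = 1.0 - ev
                l5 = 1.0 - (1.0 + v) * ev
            else:
                l3 = l5 = 1.0
            T = 3.0 * l5 * np.outer(s, s) / r**5 - l3 * np.eye(3) / r**3
            A[3 * i:3 * i + 3, 3 * j:3 * j + 3] = -T
    mu = np.linalg.solve(A, rhs)
    return mu.reshape(n, 3)
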