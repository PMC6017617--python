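"""Torsion-parameter fitting.

Rotatable-bond parameters are obtained by scanning a dihedral (typically
at 30° intervals, ~11 conformations per bond), computing the reference
quantum-chemical energy and the model energy *without* the torsion term
at each point, and least-squares fitting a six-term Fourier series

    ΔE(φ) ≈ c + Σ_{n=1..6} (V_n/2)(1 + cos(nφ − γ_n))

to the difference.  With the phases γ_n fixed (0° or 180°) the problem
is linear and solved exactly; the constant offset c is always included
because conformational-energy zeroes are arbitrary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TorsionScan",
    "FourierFit",
    "FitQuality",
    "SingularDesignError",
    "fit_torsion",
    "evaluate_fit_quality",
]


class SingularDesignError(ValueError):
    """Aliased frequencies on the scan grid; carries the design rank."""

    def __init__(self, rank: int, n_params: int):
        self.rank = rank
        self.n_params = n_params
        super().__init__(
            f"singular torsion design: rank {rank} < {n_params} parameters"
        )


@dataclass
class TorsionScan:
    """One dihedral scan: angles (deg), reference QM energies and model
    energies evaluated with the scanned torsion's parameters zeroed
    (both kcal/mol)."""

    dihedral: str
    angles: np.ndarray
    e_qm: np.ndarray
    e_mm_no_torsion: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        self.e_qm = np.asarray(self.e_qm, dtype=float).ravel()
        self.e_mm_no_torsion = np.asarray(self.e_mm_no_torsion, dtype=float).ravel()
        if not (len(self.angles) == len(self.e_qm) == len(self.e_mm_no_torsion)):
            raise ValueError("angle/energy lengths differ")
        wrapped = np.mod(self.angles, 360.0)
        if len(np.unique(np.round(wrapped, 6))) != len(wrapped):
            raise ValueError("duplicate scan angles within one period")

    @property
    def residual(self) -> np.ndarray:
        """Target of the fit: E_qm − E_mm(no torsion)."""
        return self.e_qm - self.e_mm_no_torsion


@dataclass
class FourierFit:
    amplitudes: tuple[float, ...]          # V1..V6, kcal/mol
    phases: tuple[float, ...]              # γ1..γ6, each 0 or 180 deg
    offset: float                          # c, kcal/mol
    rmse: float                            # training residual, kcal/mol

    def torsion_energy(self, angles_deg: np.ndarray) -> np.ndarray:
        """Σ (V_n/2)(1 + cos(nφ − γ_n)) — the term added to the model."""
        phi = np.radians(np.asarray(angles_deg, dtype=float))
        out = np.zeros_like(phi)
        for n, (v, g) in enumerate(zip(self.amplitudes, self.phases), start=1):
            out += 0.5 * v * (1.0 + np.cos(n * phi - math.radians(g)))
        return out

    def predict(self, angles_deg: np.ndarray) -> np.ndarray:
        """Fitted ΔE including the constant offset."""
        return self.offset + self.torsion_energy(angles_deg)


def fit_torsion(
    scan: TorsionScan,
    phases: Sequence[float] = (0.0,) * 6,
) -> FourierFit:
    """Exact linear least-squares fit of the six-term Fourier series plus
    offset to the scan's QM-minus-model residual.

    Needs at least 7 distinct angles (6 amplitudes + the offset); an
    aliased grid raises :class:`SingularDesignError` with the rank.
    """
    if len(phases) != 6:
        raise ValueError("six phases required")
    if len(scan.angles) < 7:
        raise ValueError("need at least 7 scan points for a 6-term fit")
    phi = np.radians(scan.angles)
    cols = [np.ones_like(phi)]
    for n in range(1, 7):
        cols.append(0.5 * (1.0 + np.cos(n * phi - math.radians(phases[n - 1]))))
    A = np.column_stack(cols)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise SingularDesignError(rank, A.shape[1])
    coef, *_ = np.linalg.lstsq(A, scan.residual, rcond=None)
    pred = A @ coef
    rmse = float(np.sqrt(np.mean((pred - scan.residual) ** 2)))
    return FourierFit(
        amplitudes=tuple(float(v) for v in coef[1:]),
        phases=tuple(float(g) for g in phases),
        offset=float(coef[0]),
        rmse=rmse,
    )


@dataclass
class FitQuality:
    """Model-vs-reference regression summary over pooled scans, computed
    on relative conformational energies (each scan shifted to min 0)."""

    slope: float
    intercept: float
    r2: float
    stderr: float            # standard error (RMS residual about the fit line)
    mue: float               # mean unsigned model − reference error
    n_points: int


def evaluate_fit_quality(
    scans: Sequence[TorsionScan],
    fits: Sequence[FourierFit],
) -> FitQuality:
    """Regress model conformational energies (with the fitted torsion term
    restored) against the reference energies across all scans."""
    if len(scans) != len(fits):
        raise ValueError("one fit per scan required")
    model, refq = [], []
    for scan, fit in zip(scans, fits):
        em = scan.e_mm_no_torsion + fit.torsion_energy(scan.angles)
        model.append(em - em.min())
        refq.append(scan.e_qm - scan.e_qm.min())
    x = np.concatenate(refq)
    y = np.concatenate(model)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a quality summary")
    if np.allclose(x, x[0]):
        raise ValueError("reference energies are constant; slope undefined")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return FitQuality(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        stderr=float(np.sqrt(np.mean(resid**2))),
        mue=float(np.mean(np.abs(y - x))),
        n_points=len(x),
    )
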