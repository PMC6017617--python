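"""Atomic multipole data model: polarizable sites, permanent multipoles,
local-frame definitions and the local→global rotation.

Permanent multipoles are stored per atom in a *local frame* built from
bonded neighbours, so that a single parameter set transfers across
conformations.  Two frame conventions cover almost every site in a lipid:

``z_then_x``
    the first anchor defines the z-axis, the second anchor fixes the
    zx-plane (and the positive x direction);
``bisector``
    the bisector of the two anchor directions defines z (used at sites
    whose two neighbours are symmetry-equivalent, e.g. water oxygen).

``z_only`` (terminal sites with one distinct neighbour) and ``none``
(monatomic ions) are included as degenerate conventions.

Quadrupoles follow the traceless second-moment convention
``Q = Σ q (d dᵀ − |d|²·I/3)`` in e·Å², which pairs with the potential
kernel ``φ_quad = (3/2)·r̂ᵀQr̂/r³``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PolarizableSite",
    "Multipole",
    "LocalFrameDef",
    "MultipoleSet",
    "DegenerateFrameError",
    "FrameDefinitionError",
    "build_rotation_matrix",
    "rotate_to_global",
]

_TRACE_WARN = 1e-6


class DegenerateFrameError(ValueError):
    """Raised when frame anchors are collinear or coincident with the owner."""


class FrameDefinitionError(ValueError):
    """Raised when a local frame references a missing or invalid anchor."""


@dataclass
class PolarizableSite:
    """One atom of the model: position, element and polarizability.

    ``polarizability`` is the isotropic atomic polarizability α in Å³
    entering the induced-dipole response μ_ind = α·E.
    """

    index: int
    element: str
    atomic_number: int
    position: np.ndarray
    polarizability: float = 0.0
    type_class: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.polarizability < 0:
            raise ValueError("polarizability must be non-negative")
        if self.atomic_number < 1:
            raise ValueError("atomic_number must be >= 1")

    @property
    def is_heavy(self) -> bool:
        return self.atomic_number > 1


def _detrace(q: np.ndarray) -> np.ndarray:
    return q - np.trace(q) / 3.0 * np.eye(3)


@dataclass
class Multipole:
    """Permanent charge (e), dipole (e·Å) and traceless quadrupole (e·Å²).

    Any input quadrupole is symmetrized and detraced on construction;
    deviations above 1e-6 e·Å² trigger a warning rather than silently
    passing, since they usually indicate a unit or convention mistake.
    """

    charge: float = 0.0
    dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quadrupole: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self) -> None:
        self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        q = np.asarray(self.quadrupole, dtype=float).reshape(3, 3)
        sym = 0.5 * (q + q.T)
        fixed = _detrace(sym)
        if max(np.abs(q - sym).max(), abs(np.trace(sym)) / 3.0) > _TRACE_WARN:
            warnings.warn(
                "quadrupole symmetrized/detraced by more than 1e-6 e·Å²",
                stacklevel=3,
            )
        self.quadrupole = fixed

    def copy(self) -> "Multipole":
        return Multipole(self.charge, self.dipole.copy(), self.quadrupole.copy())


FrameConvention = Literal["z_then_x", "bisector", "z_only", "none"]


@dataclass(frozen=True)
class LocalFrameDef:
    """Local-frame recipe for one site.

    ``anchor_z`` is a site index (or an index pair for ``bisector``);
    ``anchor_x`` is the in-plane anchor for ``z_then_x`` and ``bisector``.
    Anchors are interpreted as bonded neighbours of the owner.
    """

    convention: FrameConvention
    anchor_z: int | tuple[int, int] | None = None
    anchor_x: int | None = None

    def __post_init__(self) -> None:
        if self.convention == "bisector":
            if (
                not isinstance(self.anchor_z, tuple)
                or len(self.anchor_z) != 2
                or self.anchor_z[0] == self.anchor_z[1]
            ):
                raise FrameDefinitionError(
                    "bisector frame needs two distinct z anchors"
                )
        elif self.convention == "z_then_x":
            if self.anchor_z is None or self.anchor_x is None:
                raise FrameDefinitionError("z_then_x frame needs z and x anchors")
        elif self.convention == "z_only":
            if self.anchor_z is None:
                raise FrameDefinitionError("z_only frame needs a z anchor")
        elif self.convention != "none":
            raise FrameDefinitionError(
                f"unknown frame convention {self.convention!r}"
            )


@dataclass
class MultipoleSet:
    """Per-site multipoles tagged with the frame they live in."""

    multipoles: list[Multipole]
    frame_tag: Literal["local", "global"] = "local"

    def __len__(self) -> int:
        return len(self.multipoles)

    def __getitem__(self, i: int) -> Multipole:
        return self.multipoles[i]

    def copy(self) -> "MultipoleSet":
        return MultipoleSet([m.copy() for m in self.multipoles], self.frame_tag)

    @property
    def total_charge(self) -> float:
        return float(sum(m.charge for m in self.multipoles))


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise DegenerateFrameError(f"zero-length direction while building {context}")
    return v / n


def build_rotation_matrix(
    owner_index: int,
    frame: LocalFrameDef,
    coords: np.ndarray,
) -> np.ndarray:
    """Rotation matrix R whose columns are the local axes in global
    coordinates, so a local vector v maps to the global R·v.

    The z-axis points from the owner toward ``anchor_z`` (or along the
    normalized sum of the two unit anchor directions for ``bisector``);
    the x-axis is the component of the owner→anchor_x direction
    perpendicular to z.  Collinear anchors raise
    :class:`DegenerateFrameError` — there is no silent fallback.
    """
    coords = np.asarray(coords, dtype=float)
    origin = coords[owner_index]

    if frame.convention == "none":
        return np.eye(3)

    def anchor_dir(idx: int) -> np.ndarray:
        if idx == owner_index:
            raise FrameDefinitionError("anchor coincides with owning site")
        if idx < 0 or idx >= len(coords):
            raise FrameDefinitionError(f"anchor index {idx} out of range")
        return _unit(coords[idx] - origin, "z-axis")

    if frame.convention == "bisector":
        ia, ib = frame.anchor_z  # type: ignore[misc]
        z = _unit(anchor_dir(ia) + anchor_dir(ib), "bisector z-axis")
    else:
        z = anchor_dir(frame.anchor_z)  # type: ignore[arg-type]

    if frame.convention == "z_only" or frame.anchor_x is None:
        # Any perpendicular completes the frame; pick deterministically.
        seed = np.array([1.0, 0.0, 0.0])
        if abs(z @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        x = _unit(seed - (seed @ z) * z, "x-axis")
    else:
        xdir = anchor_dir(frame.anchor_x)
        perp = xdir - (xdir @ z) * z
        if np.linalg.norm(perp) < 1e-8:
            raise DegenerateFrameError(
                "z and x anchors are collinear with the owner"
            )
        x = perp / np.linalg.norm(perp)

    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def rotate_multipole(m: Multipole, R: np.ndarray) -> Multipole:
    """Rotate one multipole: charge invariant, μ' = Rμ, Q' = RQRᵀ."""
    return Multipole(m.charge, R @ m.dipole, R @ m.quadrupole @ R.T)


def rotate_to_global(
    local: MultipoleSet,
    frames: Sequence[LocalFrameDef],
    coords: np.ndarray,
) -> MultipoleSet:
    """Rotate a local-frame multipole set into the global frame.

    The charge is frame-independent; dipoles rotate as vectors and
    quadrupoles as rank-2 tensors.  Tracelessness and tensor norms are
    preserved exactly (up to rounding) because R is orthogonal.
    """
    if local.frame_tag != "local":
        raise ValueError("input MultipoleSet must be tagged local")
    if len(frames) != len(local):
        raise ValueError("one LocalFrameDef required per site")
    out = []
    for i, (m, fr) in enumerate(zip(local.multipoles, frames)):
        R = build_rotation_matrix(i, fr, coords)
        out.append(rotate_multipole(m, R))
    return MultipoleSet(out, frame_tag="global")
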