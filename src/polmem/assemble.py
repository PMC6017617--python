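"""Assemble an evaluatable :class:`~polmem.energy.System` from a
coordinate file and a parameter key file.

Parameters are matched by atom type class, the way force-field engines
resolve them: multipole local-frame anchors are bonded neighbours whose
class matches the record's z/x anchor classes (negative z class ⇒
bisector over two neighbours of the two listed classes), bonded records
match class tuples in either direction, and polarization groups grow
across a bond only when each side lists the other's class in its
polarize group list.
"""

from __future__ import annotations

import numpy as np

from .energy import BondedParams, System, VdwParams
from .io.keyfile import KeyFile
from .io.txyz import TxyzFrame
from .mpole import (
    FrameDefinitionError,
    LocalFrameDef,
    Multipole,
    MultipoleSet,
    PolarizableSite,
)
from .constants import ATOMIC_NUMBERS
from .topology import Topology

__all__ = ["system_from_files"]


def _element_of(name: str) -> str:
    for cand in (name[:2].capitalize(), name[:1].upper()):
        if cand in ATOMIC_NUMBERS:
            return cand
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _frame_for(
    i: int, rec, classes: list[int], topo: Topology
) -> LocalFrameDef:
    nbrs = sorted(topo.neighbors(i))
    if rec.z_class == 0:
        return LocalFrameDef("none")
    if rec.z_class < 0:
        za = [j for j in nbrs if classes[j] == -rec.z_class]
        xa = [j for j in nbrs if classes[j] == rec.x_class and j not in za[:1]]
        if not za or not xa:
            raise FrameDefinitionError(
                f"atom {i}: bisector anchors {-rec.z_class}/{rec.x_class} "
                "not found among bonded neighbours"
            )
        return LocalFrameDef("bisector", anchor_z=(za[0], xa[0]))
    zcand = [j for j in nbrs if classes[j] == rec.z_class]
    if not zcand:
        raise FrameDefinitionError(
            f"atom {i}: no bonded neighbour of class {rec.z_class} for z-axis"
        )
    z = zcand[0]
    if rec.x_class == 0:
        return LocalFrameDef("z_only", anchor_z=z)
    xcand = [j for j in nbrs if classes[j] == rec.x_class and j != z]
    if not xcand:
        # the x anchor may sit one bond further (bonded to the z anchor)
        xcand = [j for j in sorted(topo.neighbors(z))
                 if classes[j] == rec.x_class and j != i]
    if not xcand:
        raise FrameDefinitionError(
            f"atom {i}: no anchor of class {rec.x_class} for the zx-plane"
        )
    return LocalFrameDef("z_then_x", anchor_z=z, anchor_x=xcand[0])


def system_from_files(frame: TxyzFrame, key: KeyFile) -> System:
    n = frame.n_atoms
    classes = list(frame.types)
    bonds = frame.bond_pairs()

    pol_by_class = {p.type_class: p for p in key.polarize}
    mp_by_class = {m.type_class: m for m in key.multipoles}

    # polarization groups: a bond is inside a group iff both directions
    # list each other's class
    rotatable = []
    for i, j in bonds:
        pi = pol_by_class.get(classes[i])
        pj = pol_by_class.get(classes[j])
        linked = (
            pi is not None and pj is not None
            and classes[j] in pi.group_classes
            and classes[i] in pj.group_classes
        )
        if not linked:
            rotatable.append((i, j))
    topo = Topology(n, bonds, rotatable)

    sites, mpoles, frames_ = [], [], []
    for i in range(n):
        el = _element_of(frame.names[i])
        pol = pol_by_class.get(classes[i])
        sites.append(PolarizableSite(
            index=i, element=el, atomic_number=ATOMIC_NUMBERS[el],
            position=frame.coords[i],
            polarizability=pol.alpha if pol else 0.0,
            type_class=classes[i],
        ))
        rec = mp_by_class.get(classes[i])
        if rec is None:
            mpoles.append(Multipole())
            frames_.append(LocalFrameDef("none"))
        else:
            mpoles.append(Multipole(rec.charge, rec.dipole, rec.quadrupole))
            frames_.append(_frame_for(i, rec, classes, topo))

    bonded = BondedParams()
    bond_par = {}
    for c1, c2, kb, r0 in key.bonds:
        bond_par[(c1, c2)] = bond_par[(c2, c1)] = (kb, r0)
    for i, j in bonds:
        p = bond_par.get((classes[i], classes[j]))
        if p:
            bonded.bonds.append((i, j, *p))

    angle_par = {}
    for c1, c2, c3, ka, t0 in key.angles:
        angle_par[(c1, c2, c3)] = angle_par[(c3, c2, c1)] = (ka, t0)
    sb_par = {}
    for c1, c2, c3, ks in key.strbnds:
        sb_par[(c1, c2, c3)] = sb_par[(c3, c2, c1)] = ks
    for j in range(n):
        nb = sorted(topo.neighbors(j))
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                trip = (classes[i], classes[j], classes[k])
                if trip in angle_par:
                    bonded.angles.append((i, j, k, *angle_par[trip]))
                    if trip in sb_par:
                        bonded.stretch_bends.append((i, j, k, sb_par[trip]))

    oop_par = {}
    for c1, c2, c3, c4, ko in key.opbends:
        oop_par[(c1, c2, c3, c4)] = ko
    for c in range(n):
        nb = sorted(topo.neighbors(c))
        if len(nb) != 3:
            continue
        for d in nb:
            a, b = [x for x in nb if x != d]
            quad = (classes[c], classes[a], classes[b], classes[d])
            if quad in oop_par:
                bonded.oops.append((c, a, b, d, oop_par[quad]))

    tor_par = {}
    for c1, c2, c3, c4, amps, phases in key.torsions:
        tor_par[(c1, c2, c3, c4)] = tor_par[(c4, c3, c2, c1)] = (amps, phases)
    for j, k in bonds:
        for i in sorted(topo.neighbors(j)):
            if i == k:
                continue
            for l in sorted(topo.neighbors(k)):
                if l == j or l == i:
                    continue
                quad = (classes[i], classes[j], classes[k], classes[l])
                if quad in tor_par:
                    bonded.torsions.append((i, j, k, l, *tor_par[quad]))

    vdw = VdwParams(
        eps={c: e for c, _, e, _ in key.vdws},
        rmin={c: r for c, r, _, _ in key.vdws},
        reduction={c: red for c, _, _, red in key.vdws if red is not None},
    )
    return System(sites, topo, MultipoleSet(mpoles, "local"), frames_,
                  bonded, vdw)
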