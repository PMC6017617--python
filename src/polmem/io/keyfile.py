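"""Parameter key files (line-oriented, whitespace-delimited).

Records::

    multipole <class> <zclass> <xclass> <q>
               <mux> <muy> <muz>
               <Qxx>
               <Qxy> <Qyy>
               <Qxz> <Qyz> <Qzz>
    polarize  <class> <alpha> <thole_a> [group-classes...]
    bond      <c1> <c2> <k> <r0>
    angle     <c1> <c2> <c3> <k> <theta0>
    strbnd    <c1> <c2> <c3> <k>
    opbend    <c1> <c2> <c3> <c4> <k>
    torsion   <c1> <c2> <c3> <c4> <V1> <g1> ... <V6> <g6>
    vdw       <class> <rmin> <eps> [reduction]

A negative z-anchor class in a multipole record selects the bisector
frame convention (the two anchors are |zclass| and xclass).  Multipole
components are in e, e·Å and e·Å² (this dialect does not use TINKER's
atomic units).  Writing is canonical and ``write(read(f)) == f`` holds
bit-exactly for canonical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultipoleRecord", "PolarizeRecord", "KeyFile",
           "read_key", "write_key", "KeyParseError"]


class KeyParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class MultipoleRecord:
    type_class: int
    z_class: int            # negative ⇒ bisector (anchors |z_class| and x_class)
    x_class: int
    charge: float
    dipole: np.ndarray      # (3,)
    quadrupole: np.ndarray  # (3, 3) symmetric

    @property
    def convention(self) -> str:
        return "bisector" if self.z_class < 0 else "z_then_x"


@dataclass
class PolarizeRecord:
    type_class: int
    alpha: float
    thole_a: float
    group_classes: list[int] = field(default_factory=list)


@dataclass
class KeyFile:
    multipoles: list[MultipoleRecord] = field(default_factory=list)
    polarize: list[PolarizeRecord] = field(default_factory=list)
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    strbnds: list[tuple[int, int, int, float]] = field(default_factory=list)
    opbends: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int, tuple[float, ...], tuple[float, ...]]] = \
        field(default_factory=list)
    vdws: list[tuple[int, float, float, float | None]] = field(default_factory=list)


def read_key(path: str) -> KeyFile:
    kf = KeyFile()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    k = 0
    while k < len(lines):
        raw = lines[k]
        t = raw.split()
        if not t or raw.lstrip().startswith("#"):
            k += 1
            continue
        rec = t[0].lower()
        try:
            if rec == "multipole":
                if len(t) != 5:
                    raise KeyParseError(k + 1, "multipole header needs 4 fields")
                cls, zc, xc = int(t[1]), int(t[2]), int(t[3])
                q = float(t[4])
                dip = np.array([float(x) for x in lines[k + 1].split()])
                if dip.shape != (3,):
                    raise KeyParseError(k + 2, "dipole line needs 3 values")
                qxx = [float(x) for x in lines[k + 2].split()]
                qxy = [float(x) for x in lines[k + 3].split()]
                qxz = [float(x) for x in lines[k + 4].split()]
                if len(qxx) != 1 or len(qxy) != 2 or len(qxz) != 3:
                    raise KeyParseError(
                        k + 3, "quadrupole continuation must be 1/2/3 values"
                    )
                Q = np.array([
                    [qxx[0], qxy[0], qxz[0]],
                    [qxy[0], qxy[1], qxz[1]],
                    [qxz[0], qxz[1], qxz[2]],
                ])
                kf.multipoles.append(MultipoleRecord(cls, zc, xc, q, dip, Q))
                k += 5
                continue
            if rec == "polarize":
                kf.polarize.append(PolarizeRecord(
                    int(t[1]), float(t[2]), float(t[3]),
                    [int(x) for x in t[4:]],
                ))
            elif rec == "bond":
                kf.bonds.append((int(t[1]), int(t[2]), float(t[3]), float(t[4])))
            elif rec == "angle":
                kf.angles.append((int(t[1]), int(t[2]), int(t[3]),
                                  float(t[4]), float(t[5])))
            elif rec == "strbnd":
                kf.strbnds.append((int(t[1]), int(t[2]), int(t[3]), float(t[4])))
            elif rec == "opbend":
                kf.opbends.append((int(t[1]), int(t[2]), int(t[3]), int(t[4]),
                                   float(t[5])))
            elif rec == "torsion":
                if len(t) != 17:
                    raise KeyParseError(
                        k + 1, "torsion record needs 4 classes + 6 (V, γ) pairs"
                    )
                amps = tuple(float(t[5 + 2 * n]) for n in range(6))
                phases = tuple(float(t[6 + 2 * n]) for n in range(6))
                kf.torsions.append((int(t[1]), int(t[2]), int(t[3]), int(t[4]),
                                    amps, phases))
            elif rec == "vdw":
                red = float(t[4]) if len(t) > 4 else None
                kf.vdws.append((int(t[1]), float(t[2]), float(t[3]), red))
            else:
                raise KeyParseError(k + 1, f"unknown record {t[0]!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, KeyParseError):
                raise
            raise KeyParseError(k + 1, f"malformed {rec!r} record: {exc}") from exc
        k += 1
    return kf


def _f(v: float) -> str:
    return f"{v:.8f}"


def write_key(kf: KeyFile, path: str) -> None:
    out: list[str] = []
    for m in kf.multipoles:
        out.append(
            f"multipole {m.type_class} {m.z_class} {m.x_class} {_f(m.charge)}"
        )
        out.append("          " + " ".join(_f(x) for x in m.dipole))
        q = m.quadrupole
        out.append("          " + _f(q[0, 0]))
        out.append("          " + _f(q[0, 1]) + " " + _f(q[1, 1]))
        out.append("          " + _f(q[0, 2]) + " " + _f(q[1, 2]) + " " + _f(q[2, 2]))
    for p in kf.polarize:
        groups = "".join(f" {g}" for g in p.group_classes)
        out.append(f"polarize {p.type_class} {_f(p.alpha)} {_f(p.thole_a)}{groups}")
    for c1, c2, kb, r0 in kf.bonds:
        out.append(f"bond {c1} {c2} {_f(kb)} {_f(r0)}")
    for c1, c2, c3, ka, t0 in kf.angles:
        out.append(f"angle {c1} {c2} {c3} {_f(ka)} {_f(t0)}")
    for c1, c2, c3, ks in kf.strbnds:
        out.append(f"strbnd {c1} {c2} {c3} {_f(ks)}")
    for c1, c2, c3, c4, ko in kf.opbends:
        out.append(f"opbend {c1} {c2} {c3} {c4} {_f(ko)}")
    for c1, c2, c3, c4, amps, phases in kf.torsions:
        pairs = " ".join(f"{_f(v)} {_f(g)}" for v, g in zip(amps, phases))
        out.append(f"torsion {c1} {c2} {c3} {c4} {pairs}")
    for cls, rmin, eps, red in kf.vdws:
        tail = f" {_f(red)}" if red is not None else ""
        out.append(f"vdw {cls} {_f(rmin)} {_f(eps)}{tail}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
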