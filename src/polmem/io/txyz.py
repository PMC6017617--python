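"""TINKER-dialect Cartesian coordinate files.

Single-frame ``.txyz``::

    <natoms>  [title]
    [Lx Ly Lz alpha beta gamma]          (optional box line)
    <index> <name> <x> <y> <z> <type> [bonded indices...]

Atom numbering is 1-based in the file and 0-based in memory.  Multi-frame
``.arc`` files are frames concatenated back to back.  Writing is
canonical (fixed float format), and ``read(write(x)) == x`` holds
bit-exactly for canonical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TxyzFrame", "read_txyz", "read_arc", "write_txyz", "write_arc",
           "TxyzParseError"]


class TxyzParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class TxyzFrame:
    title: str
    names: list[str]
    coords: np.ndarray                  # (N, 3)
    types: list[int]
    bonds: list[list[int]]              # neighbor lists, 0-based, sorted
    box: np.ndarray | None = None       # (Lx, Ly, Lz)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def bond_pairs(self) -> list[tuple[int, int]]:
        out = set()
        for i, nbrs in enumerate(self.bonds):
            for j in nbrs:
                out.add((min(i, j), max(i, j)))
        return sorted(out)


def _is_box_line(tokens: list[str]) -> bool:
    if len(tokens) != 6:
        return False
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


def _parse_frame(lines: list[str], start: int) -> tuple[TxyzFrame, int]:
    k = start
    head = lines[k].split()
    if not head:
        raise TxyzParseError(k + 1, "expected atom-count header")
    try:
        n = int(head[0])
    except ValueError as exc:
        raise TxyzParseError(k + 1, f"bad atom count {head[0]!r}") from exc
    title = " ".join(head[1:])
    k += 1
    box = None
    if k < len(lines) and _is_box_line(lines[k].split()):
        vals = [float(t) for t in lines[k].split()]
        box = np.array(vals[:3])
        k += 1
    names, coords, types, bonds = [], [], [], []
    for a in range(n):
        if k >= len(lines):
            raise TxyzParseError(k + 1, "unexpected end of file inside frame")
        t = lines[k].split()
        if len(t) < 6:
            raise TxyzParseError(k + 1, "atom record needs >= 6 fields")
        try:
            names.append(t[1])
            coords.append([float(x) for x in t[2:5]])
            types.append(int(t[5]))
            bonds.append(sorted(int(x) - 1 for x in t[6:]))
        except ValueError as exc:
            raise TxyzParseError(k + 1, f"malformed atom record: {exc}") from exc
        k += 1
    return TxyzFrame(title, names, np.array(coords).reshape(n, 3),
                     types, bonds, box), k


def read_arc(path: str) -> list[TxyzFrame]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    frames = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        frame, k = _parse_frame(lines, k)
        frames.append(frame)
    if not frames:
        raise TxyzParseError(1, "no frames found")
    return frames


def read_txyz(path: str) -> TxyzFrame:
    frames = read_arc(path)
    if len(frames) != 1:
        raise ValueError(f"{path}: expected a single frame, found {len(frames)}")
    return frames[0]


def _format_frame(frame: TxyzFrame) -> str:
    out = [f"{frame.n_atoms:6d}  {frame.title}".rstrip()]
    if frame.box is not None:
        out.append(
            "  ".join(f"{v:.8f}" for v in frame.box)
            + "  90.00000000  90.00000000  90.00000000"
        )
    for i in range(frame.n_atoms):
        nbrs = "".join(f" {j + 1:5d}" for j in frame.bonds[i])
        x, y, z = frame.coords[i]
        out.append(
            f"{i + 1:6d}  {frame.names[i]:<3s}"
            f"{x:14.8f}{y:14.8f}{z:14.8f}{frame.types[i]:6d}{nbrs}"
        )
    return "\n".join(out) + "\n"


def write_txyz(frame: TxyzFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_format_frame(frame))


def write_arc(frames: list[TxyzFrame], path: str) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(_format_frame(fr))
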