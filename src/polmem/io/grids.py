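"""ESP grid tables, torsion-scan tables and profile CSV files."""

from __future__ import annotations

import numpy as np

from ..esp import ESPGrid
from ..torsion import TorsionScan

__all__ = [
    "read_esp_grid", "write_esp_grid",
    "read_torsion_scan", "write_torsion_scan",
    "write_profile_csv", "read_profile_csv",
]


def read_esp_grid(path: str) -> ESPGrid:
    """Read ``x y z phi_ref`` rows with a ``# conformer <id> units …``
    header line."""
    conformer = "unknown"
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].split()
                if tokens[:1] == ["conformer"] and len(tokens) >= 2:
                    conformer = tokens[1]
                continue
            t = line.split()
            if len(t) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'x y z phi'")
            rows.append([float(v) for v in t])
    if not rows:
        raise ValueError(f"{path}: empty grid")
    arr = np.array(rows)
    return ESPGrid(conformer, arr[:, :3], arr[:, 3])


def write_esp_grid(grid: ESPGrid, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# conformer {grid.conformer} units kcal/mol/e\n")
        for p, v in zip(grid.points, grid.reference):
            fh.write(f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {v:.8f}\n")


def read_torsion_scan(path: str, dihedral: str = "scan") -> TorsionScan:
    """Read ``angle_deg E_qm E_mm_no_torsion`` rows (``#`` comments allowed)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            t = line.split()
            if len(t) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'angle E_qm E_mm_no_torsion'"
                )
            rows.append([float(v) for v in t])
    if not rows:
        raise ValueError(f"{path}: empty scan")
    arr = np.array(rows)
    return TorsionScan(dihedral, arr[:, 0], arr[:, 1], arr[:, 2])


def write_torsion_scan(scan: TorsionScan, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# angle_deg E_qm E_mm_no_torsion\n")
        for a, eq, em in zip(scan.angles, scan.e_qm, scan.e_mm_no_torsion):
            fh.write(f"{a:.8f} {eq:.8f} {em:.8f}\n")


def write_profile_csv(profile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("z,value\n")
        for z, v in zip(profile.z, profile.values):
            fh.write(f"{z:.8f},{v:.10g}\n")


def read_profile_csv(path: str):
    from ..membrane import Profile

    z, v = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("z,"):
            raise ValueError(f"{path}: missing 'z,value' header")
        for line in fh:
            if not line.strip():
                continue
            a, b = line.split(",")
            z.append(float(a))
            v.append(float(b))
    z = np.array(z)
    width = float(z[1] - z[0]) if len(z) > 1 else 0.0
    return Profile(z, np.array(v), width)
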