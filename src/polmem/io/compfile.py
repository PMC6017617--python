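"""Bilayer composition YAML files."""

from __future__ import annotations

import numpy as np
import yaml

from ..membrane import BilayerComposition

__all__ = ["read_composition", "write_composition"]


def write_composition(comp: BilayerComposition, path: str) -> None:
    data = {
        "n_lipid": comp.n_lipid,
        "n_water": comp.n_water,
        "water_volume": comp.water_volume,
        "labels": list(comp.labels),
        "charges": [float(q) for q in comp.charges],
        "atomic_numbers": [int(z) for z in comp.atomic_numbers],
        "polarizabilities": (
            None if comp.polarizabilities is None
            else [float(a) for a in comp.polarizabilities]
        ),
        "ch_pairs": {
            chain: {int(c): [[int(a), int(b)] for a, b in pairs]
                    for c, pairs in carbons.items()}
            for chain, carbons in comp.ch_pairs.items()
        },
        "headgroup_vectors": [[int(a), int(b)]
                              for a, b in comp.headgroup_vectors],
        "terminal_carbons": [int(i) for i in comp.terminal_carbons],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_composition(path: str) -> BilayerComposition:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return BilayerComposition(
        n_lipid=int(data["n_lipid"]),
        n_water=int(data["n_water"]),
        labels=list(data["labels"]),
        charges=np.array(data["charges"], dtype=float),
        atomic_numbers=np.array(data["atomic_numbers"], dtype=int),
        polarizabilities=(
            None if data.get("polarizabilities") is None
            else np.array(data["polarizabilities"], dtype=float)
        ),
        water_volume=float(data.get("water_volume", 30.53)),
        ch_pairs={
            chain: {int(c): [tuple(p) for p in pairs]
                    for c, pairs in carbons.items()}
            for chain, carbons in data.get("ch_pairs", {}).items()
        },
        headgroup_vectors=[tuple(v) for v in data.get("headgroup_vectors", [])],
        terminal_carbons=list(data.get("terminal_carbons", [])),
    )
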