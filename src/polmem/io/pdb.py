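"""PDB structure import (via Biopython) and composition drafting."""

from __future__ import annotations

import warnings

import numpy as np

from ..constants import ATOMIC_NUMBERS

__all__ = ["read_pdb", "draft_composition"]

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "SPC"}
_ION_RESNAMES = {"NA", "SOD", "CL", "CLA", "K", "POT", "MG", "CA"}


def read_pdb(path: str):
    """Read a PDB file into (names, elements, coords, resnames, resids).

    Uses Biopython's parser; all models/chains are flattened in file
    order.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", path)
    names, elements, coords, resnames, resids = [], [], [], [], []
    for atom in structure.get_atoms():
        res = atom.get_parent()
        names.append(atom.get_name())
        el = (atom.element or atom.get_name()[:1]).capitalize()
        elements.append(el)
        coords.append(atom.get_coord())
        resnames.append(res.get_resname().strip())
        resids.append(res.get_id()[1])
    if not names:
        raise ValueError(f"{path}: no atoms found")
    return names, elements, np.array(coords, dtype=float), resnames, resids


def draft_composition(
    resnames: list[str], resids: list[int], elements: list[str]
) -> dict:
    """Draft a composition from PDB residue records.

    Returns per-atom labels ("water", "ION" or the lipid residue name),
    atomic numbers, and residue counts (``n_lipid``, ``n_water``).
    Charges, polarizabilities and C–H pairings must still be supplied by
    the user — a coordinate file cannot know them.
    """
    if not (len(resnames) == len(resids) == len(elements)):
        raise ValueError("resnames/resids/elements length mismatch")
    labels = []
    residues: set[tuple[str, int]] = set()
    for rn, rid in zip(resnames, resids):
        residues.add((rn, rid))
        if rn in _WATER_RESNAMES:
            labels.append("water")
        elif rn in _ION_RESNAMES:
            labels.append("ION")
        else:
            labels.append(rn)
    n_water = sum(1 for rn, _ in residues if rn in _WATER_RESNAMES)
    n_ion = sum(1 for rn, _ in residues if rn in _ION_RESNAMES)
    n_lipid = len(residues) - n_water - n_ion
    z = [ATOMIC_NUMBERS.get(e, 6) for e in elements]
    return {
        "labels": labels,
        "atomic_numbers": z,
        "n_lipid": n_lipid,
        "n_water": n_water,
        "n_ion": n_ion,
    }
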