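"""Molecular connectivity: bonded neighbour shells and polarization groups.

The 1-2/1-3/1-4/1-5 shells drive the connectivity scale factors applied
to permanent electrostatics and vdW.  Polarization groups are the
connected components obtained after cutting the rotatable bonds; the
permanent field acting on a site during induction excludes multipoles of
sites in the same group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology"]


@dataclass
class Topology:
    n_sites: int
    bonds: list[tuple[int, int]] = field(default_factory=list)
    rotatable_bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bonds = [tuple(sorted(b)) for b in self.bonds]
        self.rotatable_bonds = [tuple(sorted(b)) for b in self.rotatable_bonds]
        for i, j in self.bonds:
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites):
                raise ValueError(f"bond ({i},{j}) outside topology")
            if i == j:
                raise ValueError("self-bond")
        self._adj = [set() for _ in range(self.n_sites)]
        for i, j in self.bonds:
            self._adj[i].add(j)
            self._adj[j].add(i)
        self._orders: np.ndarray | None = None
        self._groups: list[int] | None = None

    def neighbors(self, i: int) -> set[int]:
        return self._adj[i]

    @property
    def bond_orders(self) -> np.ndarray:
        """Matrix of minimum bond-path lengths, capped at 5 (0 = self).

        Entry (i, j) = 1 for 1-2 pairs, 2 for 1-3, ... ; 5 means
        "separated by four or more bonds or disconnected", i.e. fully
        interacting under every scale rule.
        """
        if self._orders is None:
            n = self.n_sites
            orders = np.full((n, n), 5, dtype=int)
            np.fill_diagonal(orders, 0)
            for start in range(n):
                frontier = {start}
                seen = {start}
                for depth in range(1, 5):
                    nxt = set()
                    for u in frontier:
                        nxt |= self._adj[u]
                    nxt -= seen
                    for v in nxt:
                        orders[start, v] = min(orders[start, v], depth)
                    seen |= nxt
                    frontier = nxt
            self._orders = orders
        return self._orders

    def pair_scale_matrix(self, scale: tuple[float, float, float, float]) -> np.ndarray:
        """Per-pair scale factors from (1-2, 1-3, 1-4, 1-5) rules."""
        lut = np.array([0.0, scale[0], scale[1], scale[2], scale[3], 1.0])
        return lut[self.bond_orders]

    @property
    def polarization_groups(self) -> list[int]:
        """Group id per site: connected components after cutting the
        rotatable bonds.  Sites with no bonds form singleton groups."""
        if self._groups is None:
            cut = set(self.rotatable_bonds)
            adj = [set() for _ in range(self.n_sites)]
            for b in self.bonds:
                if b in cut:
                    continue
                i, j = b
                adj[i].add(j)
                adj[j].add(i)
            group = [-1] * self.n_sites
            gid = 0
            for start in range(self.n_sites):
                if group[start] != -1:
                    continue
                stack = [start]
                group[start] = gid
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if group[v] == -1:
                            group[v] = gid
                            stack.append(v)
                gid += 1
            self._groups = group
        return self._groups

    def group_mask(self) -> np.ndarray:
        """Boolean matrix: True where two sites share a polarization group."""
        g = np.asarray(self.polarization_groups)
        return g[:, None] == g[None, :]
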