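"""Covalent connectivity and per-residue side-chain topology.

Bonds are found in two passes: an explicit per-residue bond template from
the force-field parameter file, and a geometric fallback for everything the
template does not cover (peptide links, disulfides, ligands) using a
cell-list ("cubing") grid with cube edge twice the largest covalent radius.
Two atoms bond geometrically when their distance d satisfies
``floor < d <= r_cov(A) + r_cov(B) + tolerance`` (inclusive upper bound;
the lower floor rejects duplicated atoms).

Chi-angle definitions are data, not code: the atom quadruples live in the
parameter file, and the per-atom build order (which chi moves which atom)
is derived here from the residue bond graph.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (ForceFieldParameters, default_parameters,
                         largest_covalent_radius)
from .mmcif_io import AtomSite, Structure

__all__ = [
    "TopologyError",
    "CellGrid",
    "build_cell_grid",
    "detect_bonds",
    "SideChainTopology",
    "chi_definitions",
    "graph_distances",
]


class TopologyError(ValueError):
    """Raised for unsupported residues or malformed geometry."""


@dataclass
class CellGrid:
    """Cell-list spatial index; cell index = floor(coordinate / edge)."""

    edge: float
    positions: np.ndarray
    cells: dict[tuple[int, int, int], list[int]] = field(default_factory=dict)

    def cell_of(self, point) -> tuple[int, int, int]:
        return tuple(int(math.floor(c / self.edge)) for c in point)

    def neighbors_within(self, point, radius: float) -> list[int]:
        """Indices of stored points with distance <= radius from `point`."""
        point = np.asarray(point, dtype=float)
        reach = int(math.ceil(radius / self.edge))
        cx, cy, cz = self.cell_of(point)
        hits = []
        for ix in range(cx - reach, cx + reach + 1):
            for iy in range(cy - reach, cy + reach + 1):
                for iz in range(cz - reach, cz + reach + 1):
                    for idx in self.cells.get((ix, iy, iz), ()):
                        if np.linalg.norm(self.positions[idx] - point) <= radius:
                            hits.append(idx)
        return hits

    def candidate_pairs(self) -> set[tuple[int, int]]:
        """Index pairs sharing a 27-cell neighborhood (distance unchecked)."""
        pairs = set()
        for (ix, iy, iz), members in self.cells.items():
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        other = self.cells.get((ix + dx, iy + dy, iz + dz))
                        if not other:
                            continue
                        for i in members:
                            for j in other:
                                if i < j:
                                    pairs.add((i, j))
        return pairs

    def pairs_within(self, cutoff: float) -> set[tuple[int, int]]:
        """All index pairs at distance <= cutoff (requires cutoff <= edge)."""
        if cutoff > self.edge:
            raise TopologyError(
                f"pair cutoff {cutoff} exceeds the grid edge {self.edge}")
        out = set()
        for i, j in self.candidate_pairs():
            if np.linalg.norm(self.positions[i] - self.positions[j]) <= cutoff:
                out.add((i, j))
        return out


def build_cell_grid(atoms, edge: float) -> CellGrid:
    """Index atoms (AtomSite objects or raw coordinates) on a cubic grid."""
    if edge <= 0:
        raise TopologyError(f"grid edge must be positive, got {edge}")
    if len(atoms) == 0:
        raise TopologyError("cannot build a grid from zero atoms")
    if isinstance(atoms[0], AtomSite):
        positions = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
    else:
        positions = np.asarray(atoms, dtype=float)
    if not np.all(np.isfinite(positions)):
        raise TopologyError("non-finite coordinate passed to the cell grid")
    grid = CellGrid(edge=float(edge), positions=positions)
    for idx, pos in enumerate(positions):
        grid.cells.setdefault(grid.cell_of(pos), []).append(idx)
    return grid


def detect_bonds(structure: Structure,
                 ff: ForceFieldParameters | None = None) -> set[tuple[int, int]]:
    """Covalent bonds as pairs of indices into ``structure.atoms``.

    Explicit residue templates are applied first; atoms the templates leave
    unconnected, and all inter-residue contacts, go through the geometric
    cell-grid fallback.
    """
    ff = ff or default_parameters()
    atoms = structure.atoms
    index_of = {id(a): i for i, a in enumerate(atoms)}
    for a in atoms:
        if a.element not in ff.covalent_radius:
            raise TopologyError(
                f"element {a.element!r} of atom id {a.atom_id} is missing "
                f"from the covalent radius table")

    bonds: set[tuple[int, int]] = set()
    covered = [False] * len(atoms)

    def add(i: int, j: int) -> None:
        if i == j:
            return
        bonds.add((min(i, j), max(i, j)))

    for res in structure.residues:
        names = {}
        for a in res.atoms:
            names.setdefault(a.atom_name, a)
        for n1, n2 in ff.bonds_for(res.comp_id):
            a1, a2 = names.get(n1), names.get(n2)
            if a1 is None or a2 is None:
                continue
            i, j = index_of[id(a1)], index_of[id(a2)]
            add(i, j)
            covered[i] = covered[j] = True

    # geometric fallback
    edge = 2.0 * largest_covalent_radius(ff, structure.elements)
    grid = build_cell_grid(atoms, edge)
    residue_of = {}
    for res in structure.residues:
        for a in res.atoms:
            residue_of.setdefault(id(a), (res.asym_id, res.seq_id))
    for i, j in grid.candidate_pairs():
        if (i, j) in bonds:
            continue
        same_residue = residue_of.get(id(atoms[i])) == residue_of.get(id(atoms[j]))
        if same_residue and covered[i] and covered[j]:
            continue
        d = float(np.linalg.norm(grid.positions[i] - grid.positions[j]))
        limit = (ff.covalent_radius[atoms[i].element]
                 + ff.covalent_radius[atoms[j].element] + ff.bond_tolerance)
        if ff.bond_floor < d <= limit:
            add(i, j)
    return bonds


@dataclass
class SideChainTopology:
    """Chi definitions and incremental build order for one residue type."""

    comp_id: str
    chi_defs: list[tuple[str, str, str, str]]
    build_order: list[tuple[str, int]]   # (atom name, last chi that moves it)
    bonds: list[tuple[str, str]]         # intra-residue heavy-atom bonds
    chi_bond_types: list[str] = field(default_factory=list)

    @property
    def n_chi(self) -> int:
        return len(self.chi_defs)

    @property
    def moving_atoms(self) -> list[str]:
        return [name for name, level in self.build_order if level >= 1]

    def atoms_at_level(self, level: int) -> list[str]:
        return [name for name, lv in self.build_order if lv == level]


UNSUPPORTED = {"GLY", "ALA", "PRO"}


def chi_definitions(residue_type: str,
                    ff: ForceFieldParameters | None = None) -> SideChainTopology:
    """Chi quadruples and atom build order for a supported residue type."""
    ff = ff or default_parameters()
    comp = residue_type.upper()
    if comp in UNSUPPORTED or comp not in ff.chi_defs:
        raise TopologyError(f"unsupported residue type: {residue_type}")

    quads = list(ff.chi_defs[comp])
    bonds = ff.bonds_for(comp)
    adj: dict[str, set[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    # atoms distal to the rotated bond of each chi
    distal_sets = []
    for a1, a2, a3, a4 in quads:
        for pair in ((a1, a2), (a2, a3), (a3, a4)):
            if pair[1] not in adj.get(pair[0], ()):  # consistency check
                raise TopologyError(
                    f"chi atoms {pair} of {comp} are not bonded in the template")
        # atoms that move = component of a3 with the a2-a3 bond removed,
        # minus a3 itself (a3 sits on the rotation axis)
        seen = {a2}
        queue = deque([a3])
        while queue:
            cur = queue.popleft()
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(adj[cur] - seen)
        distal_sets.append(seen - {a2, a3})

    def level_of(name: str) -> int:
        level = 0
        for i, distal in enumerate(distal_sets, start=1):
            if name in distal:
                level = i
        return level

    # BFS from CA guarantees every atom appears after its frame atoms
    order = []
    seen = {"N", "C", "O", "OXT", "CA"}
    queue = deque(["CA"])
    while queue:
        cur = queue.popleft()
        for nxt in sorted(adj.get(cur, ())):
            if nxt not in seen:
                seen.add(nxt)
                order.append(nxt)
                queue.append(nxt)

    build_order = [(name, level_of(name)) for name in order]
    return SideChainTopology(comp, quads, build_order, bonds,
                             list(ff.chi_bond_types.get(comp, [])))


def graph_distances(topo: SideChainTopology, max_depth: int = 3
                    ) -> dict[tuple[str, str], int]:
    """Bond-graph distances (up to max_depth) between residue template atoms."""
    adj: dict[str, set[str]] = {}
    for a, b in topo.bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dist: dict[tuple[str, str], int] = {}
    for start in adj:
        frontier = {start}
        seen = {start}
        for depth in range(1, max_depth + 1):
            frontier = {n for cur in frontier for n in adj[cur]} - seen
            for n in frontier:
                dist[(start, n)] = depth
            seen |= frontier
    return dist
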