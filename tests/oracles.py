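"""Independent reference implementations used to check the package.

Everything here deliberately avoids the code paths it verifies: dihedrals
via a plain atan2 construction, rotations via the explicit Rodrigues
formula applied bond by bond with axes recomputed after every rotation,
neighbor search by all-against-all distances, and conformational scans by
full grid enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral in degrees via projections onto the central bond."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = (p3 - p2) / np.linalg.norm(p3 - p2)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(float(np.dot(np.cross(b1, v), w)),
                                   float(np.dot(v, w))))


def rodrigues(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate points about an axis line by the Rodrigues rotation formula."""
    origin = np.asarray(origin, float)
    k = np.asarray(axis, float)
    k = k / np.linalg.norm(k)
    theta = math.radians(angle_deg)
    v = np.atleast_2d(points) - origin
    rotated = (v * math.cos(theta)
               + np.cross(np.broadcast_to(k, v.shape), v) * math.sin(theta)
               + np.outer(v @ k, k) * (1.0 - math.cos(theta)))
    return rotated + origin


def side_chain_positions(coords: dict, chi_defs, bonds, chi_deg) -> dict:
    """Set chi angles by sequential axis-angle rotation, proximal first.

    After each rotation the next axis is taken from the *updated*
    coordinates, which is the physically obvious (and slow) formulation.
    """
    adj: dict[str, set] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    work = {name: np.asarray(pos, float).copy() for name, pos in coords.items()}
    for (a1, a2, a3, a4), target in zip(chi_defs, chi_deg):
        # atoms distal to the a2-a3 bond (excluding a3, which is on the axis)
        seen = {a2}
        queue = [a3]
        while queue:
            cur = queue.pop()
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(adj[cur] - seen)
        distal = sorted((seen - {a2, a3}) & set(work))

        current = dihedral(work[a1], work[a2], work[a3], work[a4])
        delta = float(target) - current
        moved = rodrigues(np.array([work[n] for n in distal]),
                          work[a2], work[a3] - work[a2], delta)
        for name, pos in zip(distal, moved):
            work[name] = pos
    return work


def brute_force_pairs(positions: np.ndarray, cutoff: float) -> set:
    """All index pairs with distance <= cutoff, O(n^2)."""
    out = set()
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(positions[i] - positions[j]) <= cutoff:
                out.add((i, j))
    return out


def exhaustive_scan(structure, key, spec, ff):
    """Full-grid enumeration of a side-chain scan: {chi: total energy}.

    Reuses the package's pair-potential formulas but none of its search
    machinery: conformations come from the sequential Rodrigues oracle and
    pairs are collected by direct double loops.
    """
    from rotascan.energy import nonbonded_terms, torsion_energy
    from rotascan.scanner import _CLASH_FLOOR, _atom_tag, reach_radius, \
        select_environment
    from rotascan.topology import chi_definitions, graph_distances

    res = structure.residue(tuple(key))
    topo = chi_definitions(res.comp_id, ff)
    env = select_environment(structure, key, reach_radius(ff), ff)
    fixed_names = {n for n, lv in topo.build_order if lv == 0}
    static = list(env) + [a for a in res.atoms if a.atom_name in fixed_names]
    stags = [_atom_tag(a, ff) for a in static]
    own = [(a.asym_id, a.seq_id) == (res.asym_id, res.seq_id) for a in static]
    dist = graph_distances(topo, 2)
    moving = topo.moving_atoms
    mtags = {n: _atom_tag(res.get_atom(n), ff) for n in moving}
    grids = [spec.chi_grid(res.comp_id, i + 1) for i in range(topo.n_chi)]

    chi0 = tuple(dihedral(*(res.coords()[n] for n in quad))
                 for quad in topo.chi_defs)
    points = list(itertools.product(*grids))
    if spec.include_initial and not any(
            all(abs(math.remainder(a - b, 360.0)) < 1e-6
                for a, b in zip(p, chi0)) for p in points):
        points.append(chi0)

    out = {}
    for chi in points:
        coords = side_chain_positions(res.coords(), topo.chi_defs,
                                      topo.bonds, chi)
        lj_v, c_v, h_v = [], [], []
        for i, m in enumerate(moving):
            for si, s in enumerate(static):
                if own[si] and dist.get((m, s.atom_name), 99) <= 2:
                    continue
                r = max(float(np.linalg.norm(coords[m] - s.pos)), _CLASH_FLOOR)
                t = nonbonded_terms(mtags[m].element, mtags[m].charge,
                                    mtags[m].role, stags[si].element,
                                    stags[si].charge, stags[si].role, r, ff)
                lj_v.append(t[0]); c_v.append(t[1]); h_v.append(t[2])
            for m2 in moving[:i]:
                if dist.get((m, m2), 99) <= 2:
                    continue
                r = max(float(np.linalg.norm(coords[m] - coords[m2])),
                        _CLASH_FLOOR)
                t = nonbonded_terms(mtags[m].element, mtags[m].charge,
                                    mtags[m].role, mtags[m2].element,
                                    mtags[m2].charge, mtags[m2].role, r, ff)
                lj_v.append(t[0]); c_v.append(t[1]); h_v.append(t[2])
        tors = [torsion_energy(chi[j], ff.torsion_terms(topo.chi_bond_types[j]))
                for j in range(topo.n_chi)]
        total = ff.w_lj * math.fsum(sorted(lj_v)) \
            + ff.w_coulomb * math.fsum(sorted(c_v)) \
            + ff.w_hbond * math.fsum(sorted(h_v)) \
            + ff.w_torsion * math.fsum(sorted(tors))
        out[tuple(float(c) for c in chi)] = total
    return out


def accepted_set(scan: dict, window: float) -> dict:
    """Acceptance filter on an exhaustive scan result."""
    e_min = min(scan.values())
    return {chi: e for chi, e in scan.items() if e <= e_min + window}
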