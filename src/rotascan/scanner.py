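"""Chi-grid conformational scan with dead-end elimination.

Each target side chain is scanned on a regular chi grid against a rigid
environment: the backbone (plus CB) atoms of surrounding residues within
the reach radius of the target CA, any HETATM atoms (ligands), and the
target's own backbone.  Side-chain atoms are added level by level (the
atoms governed by chi_1 first, then chi_2, ...), partial energies are
accumulated pairwise, and a branch is pruned as soon as its partial energy
plus an admissible best-possible-compensation bound exceeds the pruning
threshold (current best complete energy + acceptance window).  The bound
is a sum of precomputed per-atom-pair global minima of the weighted pair
potential, so pruning never removes a conformation an exhaustive scan
would accept: the DEE result equals exhaustive enumeration exactly.

For chemically 2-fold-symmetric chi angles (ASP chi2, GLU chi3, PHE/TYR
chi2) a half grid over [-90, 90) covers the full conformational space;
ASN chi2 and GLN chi3 are always scanned over the full circle because
their amide O/N atoms are chemically distinct.  The residue's measured
input chi vector is additionally evaluated off-grid, so a sterically valid
observed conformation always survives its own scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyBreakdown, torsion_energy, torsion_pair_parts
from .forcefield import ForceFieldParameters, default_parameters
from .kinematics import build_transform_chain, wrap_angle
from .mmcif_io import BACKBONE_ATOMS, Structure
from .topology import build_cell_grid, chi_definitions, graph_distances

__all__ = [
    "ScanError",
    "GridScanSpec",
    "RotamerRecord",
    "RotamerLibrary",
    "reach_radius",
    "select_environment",
    "dee_scan",
    "accept_rotamers",
    "generate_library",
    "scannable_keys",
]

logger = logging.getLogger("rotascan.scanner")

#: chi angles where chi and chi+180 are chemically indistinguishable
HALF_RANGE_CHI = {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)}

_PRUNE_MARGIN = 1e-9


class ScanError(ValueError):
    """Raised for invalid scan requests."""


@dataclass
class GridScanSpec:
    """Grid geometry and acceptance settings for a side-chain scan."""

    step: float = 10.0          # degrees; must divide 360
    window: float = 5.0         # kcal/mol above the per-residue minimum
    symmetry_reduce: bool = True
    include_initial: bool = True
    dee: bool = True
    bound_safety: float = 0.01  # admissibility slack per pair bound

    def __post_init__(self):
        if self.step <= 0:
            raise ScanError(f"scan step must be positive, got {self.step}")
        if abs(360.0 / self.step - round(360.0 / self.step)) > 1e-9:
            raise ScanError(f"scan step {self.step} does not divide 360")
        if self.window < 0:
            raise ScanError("acceptance window must be non-negative")

    def chi_grid(self, comp_id: str, chi_index: int) -> list[float]:
        if self.symmetry_reduce and (comp_id, chi_index) in HALF_RANGE_CHI:
            start, span = -90.0, 180.0
        else:
            start, span = -180.0, 360.0
        n = round(span / self.step)
        return [start + i * self.step for i in range(n)]


@dataclass
class RotamerRecord:
    """One scanned conformation: chi vector, energies, coordinates."""

    chi: tuple[float, ...]
    breakdown: EnergyBreakdown
    coords: dict[str, np.ndarray] | None = None
    accepted: bool = False
    is_initial: bool = False

    @property
    def total(self) -> float:
        return self.breakdown.total


@dataclass
class RotamerLibrary:
    """Accepted rotamers per residue key plus scan metadata."""

    entries: dict[tuple, list[RotamerRecord]] = field(default_factory=dict)
    comp_ids: dict[tuple, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def reach_radius(ff: ForceFieldParameters | None = None) -> float:
    """Furthest distance a side chain can interact from its CA.

    Ideal all-trans arginine extension + the largest van der Waals radius
    pair + the interaction boundary (cutoff_end).
    """
    from .fixtures import ideal_arg_extension

    ff = ff or default_parameters()
    return ideal_arg_extension() + 2.0 * max(ff.vdw_radius.values()) \
        + ff.cutoff_end


_ENV_NAMES = set(BACKBONE_ATOMS) | {"CB"}


def select_environment(structure: Structure, residue_key, reach: float,
                       ff: ForceFieldParameters | None = None) -> list:
    """Rigid environment atoms for one target residue.

    Mainchain (N, CA, C, O, OXT) plus CB of every other residue within
    `reach` of the target CA, all HETATM atoms within reach, and the
    target's own backbone.  Side-chain atoms of other residues beyond CB
    are never part of the environment.
    """
    ff = ff or default_parameters()
    target = structure.residue(tuple(residue_key))
    ca = target.atom("CA")
    if ca is None:
        raise ScanError(
            f"residue {residue_key} has no CA atom; cannot select environment")

    own_ids = {id(a) for a in target.atoms}
    candidates = []
    for res in structure.residues:
        if (res.asym_id, res.seq_id) == (target.asym_id, target.seq_id):
            continue
        for a in res.atoms:
            if a.record_group == "HETATM" or a.atom_name in _ENV_NAMES:
                candidates.append(a)

    env = [a for a in target.atoms if a.atom_name in BACKBONE_ATOMS]
    if candidates:
        grid = build_cell_grid(
            candidates, 2.0 * max(ff.covalent_radius.values()))
        for idx in grid.neighbors_within(ca.pos, reach):
            if id(candidates[idx]) not in own_ids:
                env.append(candidates[idx])
    return env


# -- per-atom parameters -----------------------------------------------------

@dataclass(frozen=True)
class _AtomTag:
    element: str
    charge: float
    role: str | None


def _atom_tag(atom, ff: ForceFieldParameters) -> _AtomTag:
    ff.lj(atom.element)  # fail fast on missing LJ type
    if ff.has_charge(atom.comp_id, atom.atom_name):
        q = ff.charge(atom.comp_id, atom.atom_name)
    else:
        q = 0.0
        logger.warning("atom %s:%s has no partial charge; using 0",
                       atom.comp_id, atom.atom_name)
    return _AtomTag(atom.element, q, ff.role(atom.comp_id, atom.atom_name))


#: scan-path distance floor: a (near-)coincident pair scores the potential
#: at this separation — a vast LJ repulsion — instead of raising, so probe
#: atoms placed exactly on a rotamer position reject that grid cell cleanly
_CLASH_FLOOR = 0.05


def _nonbonded(tag_a: _AtomTag, tag_b: _AtomTag, r: float,
               ff: ForceFieldParameters) -> tuple[float, float, float]:
    from .energy import nonbonded_terms
    return nonbonded_terms(tag_a.element, tag_a.charge, tag_a.role,
                           tag_b.element, tag_b.charge, tag_b.role,
                           max(r, _CLASH_FLOOR), ff)


_PAIR_MIN_CACHE: dict = {}


def _pair_min(tag_a: _AtomTag, tag_b: _AtomTag, ff: ForceFieldParameters,
              safety: float) -> float:
    """Admissible lower bound of the weighted pair potential over distance.

    Global minimum over r >= 0.5 angstroms (below which LJ repulsion
    dominates any attraction) found on a fine distance grid, clipped to
    <= 0 and lowered by a small safety slack to cover grid discretization.
    """
    key = (tag_a, tag_b, id(ff), safety) if tag_a.element <= tag_b.element \
        else (tag_b, tag_a, id(ff), safety)
    cached = _PAIR_MIN_CACHE.get(key)
    if cached is not None:
        return cached

    r = np.arange(0.5, ff.cutoff_end + 0.005, 0.005)
    eps_a, rmin_a = ff.lj(tag_a.element)
    eps_b, rmin_b = ff.lj(tag_b.element)
    eps = math.sqrt(eps_a * eps_b)
    rmin = 0.5 * (rmin_a + rmin_b)
    x6 = (rmin / r) ** 6
    lj = eps * (x6 * x6 - 2.0 * x6)
    coul = 332.0637 * tag_a.charge * tag_b.charge / (ff.dielectric * r)
    from .energy import is_hbond_pair
    if is_hbond_pair(tag_a.role, tag_b.role):
        x10 = (ff.hbond_r0 / r) ** 10
        hb = ff.hbond_epsilon * (5.0 * x10 * (ff.hbond_r0 / r) ** 2 - 6.0 * x10)
    else:
        hb = np.zeros_like(r)
    q = np.where(r <= ff.cutoff_start, 1.0,
                 np.where(r >= ff.cutoff_end, 0.0,
                          0.5 * (1.0 + np.cos(np.pi * (r - ff.cutoff_start)
                                              / (ff.cutoff_end - ff.cutoff_start)))))
    total = q * (ff.w_lj * lj + ff.w_coulomb * coul + ff.w_hbond * hb)
    value = min(float(total.min()), 0.0) - safety
    _PAIR_MIN_CACHE[key] = value
    return value


# -- the scan ----------------------------------------------------------------

def dee_scan(structure: Structure, residue_key, spec: GridScanSpec,
             ff: ForceFieldParameters | None = None, env=None,
             stats: dict | None = None) -> list[RotamerRecord]:
    """Scan one residue's chi grid; returns every completed conformation.

    With DEE enabled, branches that provably cannot enter the acceptance
    window are pruned; the surviving records passed through
    :func:`accept_rotamers` are exactly the exhaustive-scan accepted set.
    """
    ff = ff or default_parameters()
    target = structure.residue(tuple(residue_key))
    comp = target.comp_id
    topo = chi_definitions(comp, ff)
    chain = build_transform_chain(target.coords(), topo)
    k = topo.n_chi

    if env is None:
        env = select_environment(structure, residue_key, reach_radius(ff), ff)

    # static interacting atoms: the environment plus the target's fixed
    # (level-0) side-chain atoms, typically CB
    own_names = {a.atom_name for a in target.atoms}
    static_atoms = list(env)
    fixed_names = {name for name, lv in topo.build_order if lv == 0}
    for a in target.atoms:
        if a.atom_name in fixed_names:
            static_atoms.append(a)

    static_pos = np.array([[a.x, a.y, a.z] for a in static_atoms]) \
        if static_atoms else np.zeros((0, 3))
    static_tags = [_atom_tag(a, ff) for a in static_atoms]
    own_res_atom = [
        (a.asym_id, a.seq_id) == (target.asym_id, target.seq_id)
        and a.atom_name in own_names for a in static_atoms]
    static_names = [a.atom_name for a in static_atoms]

    dist = graph_distances(topo, max_depth=2)
    moving_by_level = {j: topo.atoms_at_level(j) for j in range(1, k + 1)}
    moving_names = [n for j in range(1, k + 1) for n in moving_by_level[j]]
    level_of = {n: j for j in moving_by_level for n in moving_by_level[j]}
    atoms_by_name = {a.atom_name: a for a in target.atoms}
    moving_tags = {}
    for name in moving_names:
        a = atoms_by_name.get(name)
        if a is None:
            raise ScanError(f"residue {residue_key} is missing atom {name!r}")
        moving_tags[name] = _atom_tag(a, ff)

    def excluded(moving_name: str, static_idx: int) -> bool:
        if not own_res_atom[static_idx]:
            return False
        return dist.get((moving_name, static_names[static_idx]), 99) <= 2

    def excluded_mm(name_a: str, name_b: str) -> bool:
        return dist.get((name_a, name_b), 99) <= 2

    # torsion bookkeeping per chi level
    adj: dict[str, set] = {}
    for a, b in topo.bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    torsions = []
    for (a1, a2, a3, a4), bond_type in zip(topo.chi_defs, topo.chi_bond_types):
        terms = ff.torsion_terms(bond_type)
        n_14 = max(1, len(adj[a2] - {a3}) * len(adj[a3] - {a2}))
        torsions.append((terms, n_14))

    # admissible remaining-energy bounds B[j] after completing level j
    grids = [spec.chi_grid(comp, i + 1) for i in range(k)]
    bounds = [0.0] * (k + 1)
    if spec.dee:
        # every pair involving a moving atom contributes at the level where
        # its later atom is placed; torsion terms are bounded by zero
        # (each cosine term is non-negative) unless w4 is negative
        level_bound = {j: 0.0 for j in range(1, k + 1)}
        for name in moving_names:
            tag = moving_tags[name]
            for idx in range(len(static_atoms)):
                if not excluded(name, idx):
                    level_bound[level_of[name]] += _pair_min(
                        tag, static_tags[idx], ff, spec.bound_safety)
        for ia, name_a in enumerate(moving_names):
            for name_b in moving_names[ia + 1:]:
                if excluded_mm(name_a, name_b):
                    continue
                eval_level = max(level_of[name_a], level_of[name_b])
                level_bound[eval_level] += _pair_min(
                    moving_tags[name_a], moving_tags[name_b], ff,
                    spec.bound_safety)
        if ff.w_torsion < 0:
            for j in range(1, k + 1):
                level_bound[j] += ff.w_torsion * sum(
                    t.barrier for t in torsions[j - 1][0])
        for j in range(k - 1, -1, -1):
            bounds[j] = bounds[j + 1] + level_bound[j + 1]

    records: list[RotamerRecord] = []
    best = math.inf
    n_pruned = 0
    n_leaves = 0

    lj_parts: list[float] = []
    coul_parts: list[float] = []
    hb_parts: list[float] = []
    tor_parts: list[float] = []

    def level_contrib(j: int, coords_j: dict) -> int:
        """Append level-j pair/torsion contributions; returns #values pushed."""
        pushed = 0
        for name in moving_by_level[j]:
            p = coords_j[name]
            tag = moving_tags[name]
            for idx in range(len(static_atoms)):
                if excluded(name, idx):
                    continue
                r = float(np.linalg.norm(p - static_pos[idx]))
                lj, coul, hb = _nonbonded(tag, static_tags[idx], r, ff)
                lj_parts.append(lj)
                coul_parts.append(coul)
                hb_parts.append(hb)
                pushed += 1
            # placed holds lower levels plus same-level atoms added earlier
            # in this loop, so every moving-moving pair is counted once
            for other, opos in placed.items():
                if excluded_mm(name, other):
                    continue
                r = float(np.linalg.norm(p - opos))
                lj, coul, hb = _nonbonded(tag, moving_tags[other], r, ff)
                lj_parts.append(lj)
                coul_parts.append(coul)
                hb_parts.append(hb)
                pushed += 1
            placed[name] = p
        return pushed

    def weighted_running() -> float:
        return ff.w_lj * math.fsum(lj_parts) \
            + ff.w_coulomb * math.fsum(coul_parts) \
            + ff.w_hbond * math.fsum(hb_parts) \
            + ff.w_torsion * math.fsum(tor_parts)

    def leaf_record(chi: tuple, is_initial: bool) -> RotamerRecord:
        breakdown = EnergyBreakdown.combine(
            math.fsum(sorted(lj_parts)), math.fsum(sorted(coul_parts)),
            math.fsum(sorted(hb_parts)), math.fsum(sorted(tor_parts)), ff)
        coords = {}
        for a in target.atoms:
            coords[a.atom_name] = placed[a.atom_name].copy() \
                if a.atom_name in placed else a.pos
        return RotamerRecord(chi=chi, breakdown=breakdown, coords=coords,
                             is_initial=is_initial)

    placed: dict[str, np.ndarray] = {}

    def walk(j: int, chi_prefix: tuple):
        nonlocal best, n_pruned, n_leaves
        for value in grids[j - 1]:
            chi = chi_prefix + (value,)
            coords_j = chain.evaluate(chi, up_to=j)
            n_lists = (len(lj_parts), len(tor_parts))
            placed_before = dict(placed)
            pushed = level_contrib(j, coords_j)
            parts = torsion_pair_parts(
                torsion_energy(value, torsions[j - 1][0]), torsions[j - 1][1])
            tor_parts.extend(parts)

            partial = weighted_running()
            if spec.dee and partial + bounds[j] > best + spec.window + _PRUNE_MARGIN:
                n_pruned += 1
            elif j == k:
                n_leaves += 1
                rec = leaf_record(chi, False)
                records.append(rec)
                best = min(best, rec.total)
            else:
                walk(j + 1, chi)

            del lj_parts[n_lists[0]:]
            del coul_parts[n_lists[0]:]
            del hb_parts[n_lists[0]:]
            del tor_parts[n_lists[1]:]
            placed.clear()
            placed.update(placed_before)

    walk(1, ())

    if spec.include_initial:
        chi0 = tuple(wrap_angle(c) for c in chain.initial_chi)
        already = any(
            all(abs(wrap_angle(a - b)) < 1e-6 for a, b in zip(r.chi, chi0))
            for r in records)
        if not already:
            placed.clear()
            coords_full = chain.evaluate(chi0)
            for j in range(1, k + 1):
                level_contrib(j, coords_full)
                parts = torsion_pair_parts(
                    torsion_energy(chi0[j - 1], torsions[j - 1][0]),
                    torsions[j - 1][1])
                tor_parts.extend(parts)
            records.append(leaf_record(chi0, True))
            lj_parts.clear(); coul_parts.clear()
            hb_parts.clear(); tor_parts.clear()
            placed.clear()

    if stats is not None:
        stats.update({"pruned_branches": n_pruned, "leaves": n_leaves,
                      "records": len(records)})
    if not records:
        raise ScanError(f"scan of {residue_key} produced no conformations")
    return records


def accept_rotamers(records: list[RotamerRecord],
                    window: float) -> list[RotamerRecord]:
    """Keep records with total <= min(total) + window, sorted by energy.

    Energy ties break on the chi tuple so output order is deterministic.
    """
    if not records:
        raise ScanError("cannot accept rotamers from an empty record list")
    e_min = min(r.total for r in records)
    kept = [r for r in records if r.total <= e_min + window]
    kept.sort(key=lambda r: (r.total, r.chi))
    for r in kept:
        r.accepted = True
    return kept


def scannable_keys(structure: Structure,
                   ff: ForceFieldParameters | None = None) -> list[tuple]:
    """Keys of all residues with at least one scannable chi angle."""
    ff = ff or default_parameters()
    return [res.key for res in structure.residues
            if res.comp_id in ff.chi_defs
            and all(a.record_group == "ATOM" for a in res.atoms)]


def generate_library(structure: Structure, keys=None,
                     spec: GridScanSpec | None = None,
                     ff: ForceFieldParameters | None = None) -> RotamerLibrary:
    """Scan the requested residues and assemble their rotamer library."""
    ff = ff or default_parameters()
    spec = spec or GridScanSpec()
    if keys is None:
        keys = scannable_keys(structure, ff)

    lib = RotamerLibrary(meta={
        "step": spec.step, "window": spec.window,
        "symmetry_reduce": spec.symmetry_reduce, "dee": spec.dee,
        "pruned_branches": 0, "leaves": 0,
    })
    reach = reach_radius(ff)
    for key in keys:
        key = tuple(key)
        stats: dict = {}
        env = select_environment(structure, key, reach, ff)
        records = dee_scan(structure, key, spec, ff, env=env, stats=stats)
        accepted = accept_rotamers(records, spec.window)
        lib.entries[key] = accepted
        lib.comp_ids[key] = structure.residue(key).comp_id
        lib.meta["pruned_branches"] += stats["pruned_branches"]
        lib.meta["leaves"] += stats["leaves"]
        logger.info("residue %s: %d/%d rotamers accepted, %d branches pruned",
                    key, len(accepted), stats["records"],
                    stats["pruned_branches"])
    return lib
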