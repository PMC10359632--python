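"""Symmetry-aware evaluation of rotamer libraries against observed residues.

The central quantities are the best-case RMSD (bcRMSD) — the minimum, over
all rotamers a library offers for a residue and over the chemically valid
side-chain atom-name permutations, of the root-mean-square deviation of the
side-chain heavy atoms — and the best-case dihedral angles (bcDA), the
signed circular chi differences of the bcRMSD-selected rotamer.  RMSD is
computed in the fixed structure frame with no superposition: candidates are
built on the observed backbone, so a superposition step would mask exactly
the displacement a protein modeller cares about.

Chemically 2-fold symmetric groups make atom naming ambiguous: ASP chi2
(OD1/OD2), GLU chi3 (OE1/OE2) and the PHE/TYR ring chi2 (CD1/CD2,
CE1/CE2) are always folded.  The amide O/N of ASN chi2 and GLN chi3 are
chemically distinct but often indistinguishable in electron density, so
their folding applies only when the benchmarking flag is set.

Outlier rules: a residue is flagged when bcRMSD >= 0.1 angstrom
(inclusive), and angle-flagged when it is flagged and some |bcDA| exceeds
10 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forcefield import ForceFieldParameters, default_parameters
from .kinematics import build_transform_chain, measure_dihedral, wrap_angle
from .mmcif_io import Residue, Structure
from .topology import TopologyError, chi_definitions

__all__ = [
    "EvaluationError",
    "SymmetryRule",
    "ComparisonRecord",
    "symmetry_rules",
    "bc_rmsd",
    "bc_da",
    "rotamer_count",
    "flag_outliers",
    "compare_library",
    "library_from_chi_table",
    "report_tsv",
    "RMSD_OUTLIER_THRESHOLD",
    "ANGLE_OUTLIER_THRESHOLD",
]

RMSD_OUTLIER_THRESHOLD = 0.1   # angstroms, inclusive
ANGLE_OUTLIER_THRESHOLD = 10.0  # degrees, exclusive

SCOPE_ALWAYS = "always"
SCOPE_BENCHMARKING = "benchmarking"


class EvaluationError(ValueError):
    """Raised for mismatched residues or malformed comparisons."""


@dataclass(frozen=True)
class SymmetryRule:
    """A chi <-> chi + 180 equivalence and the atom swap realizing it."""

    comp_id: str
    chi_index: int
    permutation: tuple[tuple[str, str], ...]   # name swaps, involutive
    scope: str = SCOPE_ALWAYS

    def applies(self, benchmarking: bool) -> bool:
        return self.scope == SCOPE_ALWAYS or benchmarking

    def permute(self, coords: dict) -> dict:
        mapping = {}
        for a, b in self.permutation:
            mapping[a] = b
            mapping[b] = a
        return {mapping.get(name, name): pos for name, pos in coords.items()}


_RULES: dict[str, list[SymmetryRule]] = {
    "ASP": [SymmetryRule("ASP", 2, (("OD1", "OD2"),))],
    "GLU": [SymmetryRule("GLU", 3, (("OE1", "OE2"),))],
    "PHE": [SymmetryRule("PHE", 2, (("CD1", "CD2"), ("CE1", "CE2")))],
    "TYR": [SymmetryRule("TYR", 2, (("CD1", "CD2"), ("CE1", "CE2")))],
    "ASN": [SymmetryRule("ASN", 2, (("OD1", "ND2"),), SCOPE_BENCHMARKING)],
    "GLN": [SymmetryRule("GLN", 3, (("OE1", "NE2"),), SCOPE_BENCHMARKING)],
}


def symmetry_rules(residue_type: str) -> list[SymmetryRule]:
    """Side-chain symmetry rules for a supported residue type."""
    comp = residue_type.upper()
    try:
        chi_definitions(comp)
    except TopologyError as exc:
        raise EvaluationError(str(exc)) from exc
    return list(_RULES.get(comp, []))


def _side_chain_coords(coords: dict, comp_id: str,
                       ff: ForceFieldParameters) -> dict:
    topo = chi_definitions(comp_id, ff)
    names = [name for name, _ in topo.build_order]
    missing = [n for n in names if n not in coords]
    if missing:
        raise EvaluationError(
            f"missing side-chain atoms of {comp_id}: {missing}")
    return {n: np.asarray(coords[n], dtype=float) for n in names}


def _observed_coords(observed) -> tuple[dict, str]:
    if isinstance(observed, Residue):
        return observed.coords(), observed.comp_id
    raise EvaluationError("observed must be a Residue")


def _rmsd(a: dict, b: dict, names) -> float:
    sq = [float(np.sum((a[n] - b[n]) ** 2)) for n in names]
    return math.sqrt(math.fsum(sq) / len(sq))


def _variants(coords: dict, rules, benchmarking: bool):
    """All symmetry images of a coordinate set (each rule on or off)."""
    active = [r for r in rules if r.applies(benchmarking)]
    variants = [(coords, ())]
    for rule in active:
        variants += [(rule.permute(c), flips + (rule.chi_index,))
                     for c, flips in variants]
    return variants


def bc_rmsd(observed, candidates, rules=None, benchmarking: bool = False,
            ff: ForceFieldParameters | None = None) -> tuple[float, int]:
    """Best-case RMSD over candidates and symmetry permutations.

    Returns (rmsd in angstroms, index of the best candidate).  No
    superposition is performed: coordinates are compared in the shared
    structure frame.
    """
    ff = ff or default_parameters()
    obs_coords, comp = _observed_coords(observed)
    if not candidates:
        raise EvaluationError("no candidate rotamers to compare")
    if rules is None:
        rules = symmetry_rules(comp)
    obs_side = _side_chain_coords(obs_coords, comp, ff)
    names = sorted(obs_side)

    best = math.inf
    best_idx = -1
    for idx, rec in enumerate(candidates):
        cand = rec.coords if hasattr(rec, "coords") else rec
        if cand is None:
            raise EvaluationError(f"candidate {idx} has no coordinates")
        cand_side = _side_chain_coords(cand, comp, ff)
        if set(cand_side) != set(obs_side):
            raise EvaluationError(
                f"candidate {idx} atom names do not match observed: "
                f"{sorted(set(cand_side) ^ set(obs_side))}")
        for variant, _ in _variants(cand_side, rules, benchmarking):
            value = _rmsd(obs_side, variant, names)
            if value < best:
                best = value
                best_idx = idx
    return best, best_idx


def _measure_chi(coords: dict, comp: str, ff) -> tuple[float, ...]:
    topo = chi_definitions(comp, ff)
    return tuple(measure_dihedral(*(coords[n] for n in quad))
                 for quad in topo.chi_defs)


def fold_difference(delta: float) -> float:
    """Map a circular difference into the 180-degree equivalence class."""
    d = wrap_angle(delta)
    if d > 90.0:
        d -= 180.0
    elif d <= -90.0:
        d += 180.0
    return d


def bc_da(observed, candidates, rules=None, benchmarking: bool = False,
          ff: ForceFieldParameters | None = None) -> tuple[float, ...]:
    """Signed circular chi differences of the bcRMSD-selected rotamer.

    Differences are wrapped into (-180, 180]; chi angles covered by an
    applicable symmetry rule are folded into their 180-degree equivalence
    class first (range (-90, 90]).
    """
    ff = ff or default_parameters()
    obs_coords, comp = _observed_coords(observed)
    if rules is None:
        rules = symmetry_rules(comp)
    _, idx = bc_rmsd(observed, candidates, rules, benchmarking, ff)
    rec = candidates[idx]

    obs_chi = _measure_chi(obs_coords, comp, ff)
    if hasattr(rec, "chi") and rec.chi:
        cand_chi = tuple(rec.chi)
    else:
        cand = rec.coords if hasattr(rec, "coords") else rec
        cand_chi = _measure_chi(cand, comp, ff)

    folded = {r.chi_index for r in rules if r.applies(benchmarking)}
    diffs = []
    for i, (c, o) in enumerate(zip(cand_chi, obs_chi), start=1):
        # observed minus predicted, wrapped the short way around the circle
        delta = wrap_angle(o - c)
        if i in folded:
            delta = fold_difference(delta)
        diffs.append(delta)
    return tuple(diffs)


def rotamer_count(entry) -> int:
    """Number of accepted rotamers in one library entry."""
    if entry is None:
        raise EvaluationError("no library entry given")
    return sum(1 for rec in entry if getattr(rec, "accepted", True))


@dataclass
class ComparisonRecord:
    """Per-residue evaluation result of one library."""

    residue_key: tuple
    comp_id: str
    library: str
    bcrmsd: float
    bcda: tuple[float, ...]
    count: int
    rmsd_outlier: bool = False
    angle_outlier: bool = False


def flag_outliers(record: ComparisonRecord) -> tuple[bool, bool]:
    """Apply the analysis thresholds: bcRMSD >= 0.1 A, then |bcDA| > 10 deg."""
    rmsd_flag = record.bcrmsd >= RMSD_OUTLIER_THRESHOLD
    angle_flag = rmsd_flag and any(abs(d) > ANGLE_OUTLIER_THRESHOLD
                                   for d in record.bcda)
    record.rmsd_outlier = rmsd_flag
    record.angle_outlier = angle_flag
    return rmsd_flag, angle_flag


def compare_library(structure: Structure, library, benchmarking: bool = False,
                    library_name: str = "rotascan",
                    ff: ForceFieldParameters | None = None
                    ) -> list[ComparisonRecord]:
    """Evaluate every library entry against its observed residue."""
    ff = ff or default_parameters()
    out = []
    for key in sorted(library.entries, key=lambda k: (k[0], k[1], k[2])):
        observed = structure.residue(key)
        candidates = library.entries[key]
        rules = symmetry_rules(observed.comp_id)
        rmsd, _ = bc_rmsd(observed, candidates, rules, benchmarking, ff)
        da = bc_da(observed, candidates, rules, benchmarking, ff)
        rec = ComparisonRecord(
            residue_key=key, comp_id=observed.comp_id, library=library_name,
            bcrmsd=rmsd, bcda=da, count=rotamer_count(candidates))
        flag_outliers(rec)
        out.append(rec)
    return out


def library_from_chi_table(structure: Structure, table,
                           ff: ForceFieldParameters | None = None):
    """Realize an external chi table as candidate coordinates.

    ``table`` rows are (residue_type, chi1..chik) tuples (a trailing weight
    column is ignored).  For every matching residue of the structure the
    chi vectors are applied to the observed side chain via its transform
    chain, i.e. candidates keep the residue's internal geometry and
    backbone frame and only the dihedral angles are imposed.
    """
    from .energy import EnergyBreakdown
    from .scanner import RotamerLibrary, RotamerRecord

    ff = ff or default_parameters()
    by_type: dict[str, list[tuple[float, ...]]] = {}
    for row in table:
        comp = str(row[0]).upper()
        k = len(ff.chi_defs.get(comp, ()))
        if k == 0:
            raise EvaluationError(f"chi table references unsupported type {comp}")
        chi = tuple(float(v) for v in row[1:1 + k])
        by_type.setdefault(comp, []).append(chi)

    lib = RotamerLibrary(meta={"source": "chi-table"})
    for res in structure.residues:
        chis = by_type.get(res.comp_id)
        if not chis:
            continue
        topo = chi_definitions(res.comp_id, ff)
        chain = build_transform_chain(res.coords(), topo)
        records = []
        for chi in chis:
            coords = dict(res.coords())
            coords.update(chain.evaluate(chi))
            records.append(RotamerRecord(
                chi=chi, breakdown=EnergyBreakdown(), coords=coords,
                accepted=True))
        lib.entries[res.key] = records
        lib.comp_ids[res.key] = res.comp_id
    return lib


_TSV_HEADER = ("asym_id", "seq_id", "alt_loc", "comp_id", "library",
               "bcrmsd", "bcda_1", "bcda_2", "bcda_3", "bcda_4",
               "rotamer_count", "rmsd_outlier", "angle_outlier")


def report_tsv(records: list[ComparisonRecord]) -> str:
    """Tab-separated evaluation report (fixed, versioned column set)."""
    lines = ["\t".join(_TSV_HEADER)]
    for r in records:
        da = [f"{d:.3f}" for d in r.bcda] + ["."] * (4 - len(r.bcda))
        lines.append("\t".join([
            r.residue_key[0], str(r.residue_key[1]), r.residue_key[2] or ".",
            r.comp_id, r.library, f"{r.bcrmsd:.4f}", *da, str(r.count),
            str(int(r.rmsd_outlier)), str(int(r.angle_outlier))]))
    return "\n".join(lines) + "\n"
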