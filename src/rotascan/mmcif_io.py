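"""PDBx/mmCIF input and output.

Reading extracts the ``atom_site`` category of a PDBx/mmCIF (v5) file into a
light-weight :class:`Structure`: a flat atom list plus residues grouped by
(chain, sequence number, alternate location).  The twelve ``label_*`` /
coordinate items are mandatory; everything else in the file is ignored.
Writing emits generated rotamer libraries as an ``atom_site`` loop (one
model per rotamer) plus a ``rotascan_rotamer`` loop carrying the chi angles
(degrees) and the energy-term breakdown of every rotamer, so a library file
is re-readable both as coordinates and as metadata.

Alternate locations are kept as separate residues sharing their blank-altloc
atoms; only the first model is read unless another is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "MmcifError",
    "AtomSite",
    "Residue",
    "Structure",
    "read_structure",
    "write_structure",
    "write_library",
    "read_library",
]

MANDATORY_ITEMS = (
    "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
    "label_comp_id", "label_asym_id", "label_seq_id",
    "Cartn_x", "Cartn_y", "Cartn_z", "pdbx_PDB_model_num",
)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


class MmcifError(ValueError):
    """Raised for malformed or incomplete mmCIF input."""


@dataclass
class AtomSite:
    """One row of the atom_site category (coordinates in angstroms)."""

    record_group: str          # ATOM or HETATM
    atom_id: int
    element: str
    atom_name: str
    alt_loc: str               # '' when absent
    comp_id: str
    asym_id: str
    seq_id: int
    x: float
    y: float
    z: float
    model_num: int = 1

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def set_pos(self, pos) -> None:
        self.x, self.y, self.z = (float(v) for v in pos)

    def copy(self) -> "AtomSite":
        return replace(self)


@dataclass
class Residue:
    """Atoms of one residue (one alternate location, if any)."""

    comp_id: str
    asym_id: str
    seq_id: int
    alt_loc: str = ""
    atoms: list[AtomSite] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.asym_id, self.seq_id, self.alt_loc)

    def atom(self, name: str) -> AtomSite | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def get_atom(self, name: str) -> AtomSite:
        a = self.atom(name)
        if a is None:
            raise MmcifError(
                f"residue {self.asym_id}{self.seq_id} {self.comp_id} has no "
                f"atom {name!r}")
        return a

    def coords(self) -> dict[str, np.ndarray]:
        return {a.atom_name: a.pos for a in self.atoms}


@dataclass
class Structure:
    """All atoms of one model, with residues in chain order."""

    atoms: list[AtomSite] = field(default_factory=list)
    residues: list[Residue] = field(default_factory=list)

    def residue(self, key: tuple[str, int, str]) -> Residue:
        for res in self.residues:
            if res.key == key:
                return res
        # a blank alt_loc in the key matches a residue that has alternates
        asym, seq, alt = key
        if alt == "":
            for res in self.residues:
                if (res.asym_id, res.seq_id) == (asym, seq):
                    return res
        raise MmcifError(f"no residue with key {key}")

    def copy(self) -> "Structure":
        return build_structure([a.copy() for a in self.atoms])

    @property
    def elements(self) -> set[str]:
        return {a.element for a in self.atoms}


def build_structure(atoms: list[AtomSite]) -> Structure:
    """Group atoms into residues by (asym_id, seq_id), splitting alternates.

    Atoms with a blank alt_loc are shared by every alternate of their
    residue; each distinct alt_loc value becomes its own residue entry.
    """
    seen = set()
    for a in atoms:
        ident = (a.atom_id, a.model_num)
        if ident in seen:
            raise MmcifError(f"duplicate atom id {a.atom_id} in model {a.model_num}")
        seen.add(ident)
        if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
            raise MmcifError(f"non-finite coordinates for atom id {a.atom_id}")

    groups: dict[tuple, list[AtomSite]] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.asym_id, a.seq_id, a.comp_id)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(a)

    residues = []
    for asym, seq, comp in order:
        group = groups[(asym, seq, comp)]
        alts = sorted({a.alt_loc for a in group if a.alt_loc})
        if not alts:
            residues.append(Residue(comp, asym, seq, "", list(group)))
        else:
            shared = [a for a in group if not a.alt_loc]
            for alt in alts:
                own = [a for a in group if a.alt_loc == alt]
                residues.append(Residue(comp, asym, seq, alt, shared + own))
    residues.sort(key=lambda r: (r.asym_id, r.seq_id, r.alt_loc))
    return Structure(atoms=list(atoms), residues=residues)


def _find_atom_site_block(doc) -> "gemmi.cif.Block":
    for block in doc:
        if block.find_loop("_atom_site.id"):
            return block
        if block.find_value("_atom_site.id") is not None:
            return block
    raise MmcifError("no atom_site category found in input")


def read_structure(cif_text: str, model: int | None = None) -> Structure:
    """Read atoms of one model (default: the first model in the file)."""
    try:
        doc = gemmi.cif.read_string(cif_text)
    except (RuntimeError, ValueError) as exc:
        raise MmcifError(f"cannot parse mmCIF input: {exc}") from exc
    if len(doc) == 0:
        raise MmcifError("no data block found in input")
    block = _find_atom_site_block(doc)

    columns = {}
    for item in MANDATORY_ITEMS:
        col = block.find_loop(f"_atom_site.{item}")
        if not col:
            value = block.find_value(f"_atom_site.{item}")
            if value is None:
                raise MmcifError(f"mandatory atom_site item missing: {item}")
            col = [value]
        columns[item] = list(col)

    n = len(columns["id"])
    atoms = []
    for i in range(n):
        def txt(item, i=i):
            return gemmi.cif.as_string(columns[item][i])

        def num(item, conv, i=i):
            raw = columns[item][i]
            try:
                return conv(gemmi.cif.as_string(raw))
            except (TypeError, ValueError):
                raise MmcifError(
                    f"malformed numeric value {raw!r} for _atom_site.{item} "
                    f"in row {i + 1}")

        atoms.append(AtomSite(
            record_group=txt("group_PDB"),
            atom_id=num("id", int),
            element=txt("type_symbol").upper(),
            atom_name=txt("label_atom_id"),
            alt_loc=txt("label_alt_id"),
            comp_id=txt("label_comp_id"),
            asym_id=txt("label_asym_id"),
            seq_id=num("label_seq_id", int),
            x=num("Cartn_x", float),
            y=num("Cartn_y", float),
            z=num("Cartn_z", float),
            model_num=num("pdbx_PDB_model_num", int),
        ))

    if not atoms:
        raise MmcifError("atom_site category is empty")
    wanted = model if model is not None else atoms[0].model_num
    atoms = [a for a in atoms if a.model_num == wanted]
    if not atoms:
        raise MmcifError(f"no atoms found for model {wanted}")
    return build_structure(atoms)


_ATOM_SITE_TAGS = list(MANDATORY_ITEMS)


def _atom_row(a: AtomSite) -> list[str]:
    return [
        a.record_group, str(a.atom_id), a.element, a.atom_name,
        a.alt_loc or ".", a.comp_id, a.asym_id, str(a.seq_id),
        f"{a.x:.3f}", f"{a.y:.3f}", f"{a.z:.3f}", str(a.model_num),
    ]


def write_structure(structure: Structure, block_name: str = "rotascan") -> str:
    """Serialize a structure as a minimal atom_site loop (3-decimal coords)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    loop = block.init_loop("_atom_site.", _ATOM_SITE_TAGS)
    for a in structure.atoms:
        loop.add_row(_atom_row(a))
    return doc.as_string()


def write_library(lib, block_name: str = "rotascan_library") -> str:
    """Serialize a rotamer library to mmCIF text.

    Every rotamer becomes one model of the atom_site loop (full residue
    coordinates) and one row of the ``rotascan_rotamer`` loop holding its
    rank, chi angles and energy terms.
    """
    if not lib.entries or not any(lib.entries.values()):
        raise MmcifError("cannot write an empty rotamer library")

    atom_rows: list[list[str]] = []
    rot_rows: list[list[str]] = []
    model = 0
    atom_id = 0
    for key in sorted(lib.entries, key=lambda k: (k[0], k[1], k[2])):
        asym, seq, alt = key
        comp = lib.comp_ids[key]
        for rank, rec in enumerate(lib.entries[key], start=1):
            if rec.coords is None or not rec.coords:
                raise MmcifError(
                    f"rotamer {rank} of {asym}{seq} has no coordinates")
            model += 1
            for name in rec.coords:
                atom_id += 1
                pos = rec.coords[name]
                atom_rows.append(_atom_row(AtomSite(
                    "ATOM", atom_id, _element_from_name(name), name,
                    alt, comp, asym, seq,
                    float(pos[0]), float(pos[1]), float(pos[2]), model)))
            chis = [f"{c:.4f}" for c in rec.chi] + ["."] * (4 - len(rec.chi))
            b = rec.breakdown
            rot_rows.append([
                str(model), str(model), asym, str(seq), alt or ".", comp,
                str(rank), *chis,
                f"{b.lj:.9g}", f"{b.coulomb:.9g}", f"{b.hbond:.9g}",
                f"{b.torsion:.9g}", f"{b.total:.9g}",
            ])

    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    atom_loop = block.init_loop("_atom_site.", _ATOM_SITE_TAGS)
    for row in atom_rows:
        atom_loop.add_row(row)
    rot_loop = block.init_loop("_rotascan_rotamer.", [
        "id", "model_num", "asym_id", "seq_id", "alt_loc", "comp_id", "rank",
        "chi_1", "chi_2", "chi_3", "chi_4",
        "energy_lj", "energy_coulomb", "energy_hbond", "energy_torsion",
        "energy_total",
    ])
    for row in rot_rows:
        rot_loop.add_row(row)
    return doc.as_string()


def _element_from_name(name: str) -> str:
    from .forcefield import element_of_atom
    return element_of_atom(name)


def read_library(cif_text: str):
    """Re-read a library written by :func:`write_library`."""
    from .energy import EnergyBreakdown
    from .scanner import RotamerLibrary, RotamerRecord

    try:
        doc = gemmi.cif.read_string(cif_text)
    except (RuntimeError, ValueError) as exc:
        raise MmcifError(f"cannot parse library file: {exc}") from exc
    if len(doc) == 0:
        raise MmcifError("no data block found in library input")
    block = doc[0]

    table = block.find("_rotascan_rotamer.", [
        "model_num", "asym_id", "seq_id", "alt_loc", "comp_id", "rank",
        "chi_1", "chi_2", "chi_3", "chi_4",
        "energy_lj", "energy_coulomb", "energy_hbond", "energy_torsion",
        "energy_total"])
    if len(table) == 0:
        raise MmcifError("no rotascan_rotamer category found")

    # atoms grouped by model number
    atoms_by_model: dict[int, dict[str, np.ndarray]] = {}
    col = {item: list(block.find_loop(f"_atom_site.{item}"))
           for item in MANDATORY_ITEMS}
    for i in range(len(col["id"])):
        m = int(col["pdbx_PDB_model_num"][i])
        atoms_by_model.setdefault(m, {})[
            gemmi.cif.as_string(col["label_atom_id"][i])] = np.array([
                float(col["Cartn_x"][i]), float(col["Cartn_y"][i]),
                float(col["Cartn_z"][i])])

    lib = RotamerLibrary()
    for row in table:
        model = int(row[0])
        alt = gemmi.cif.as_string(row[3])
        key = (gemmi.cif.as_string(row[1]), int(row[2]),
               "" if alt in (".", "?") else alt)
        chi = tuple(float(row[6 + i]) for i in range(4)
                    if gemmi.cif.as_string(row[6 + i]) not in (".", "?", ""))
        breakdown = EnergyBreakdown(
            lj=float(row[10]), coulomb=float(row[11]), hbond=float(row[12]),
            torsion=float(row[13]), total=float(row[14]))
        rec = RotamerRecord(chi=chi, breakdown=breakdown,
                            coords=atoms_by_model.get(model, {}),
                            accepted=True)
        lib.comp_ids[key] = gemmi.cif.as_string(row[4])
        lib.entries.setdefault(key, []).append(rec)
    return lib
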