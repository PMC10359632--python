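"""Force-field parameters: radii, Lennard-Jones, charges, H-bonds, torsions.

All physical constants used by bond detection and energy scoring live in a
single parameter object loaded from a CIF-style text file.  A frozen default
file ships with the package (``data/parameters.cif``) so the tool runs with
no external input: Pyykko covalent single-bond radii for connectivity,
Amber-derived Lennard-Jones and partial-charge snapshots per element / per
(residue, atom), a 12-10 hydrogen-bond well on flagged heavy atoms, 3-fold
cosine torsion terms keyed by the rotated bond's elements, and the four
term weights of the total-energy combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import gemmi

__all__ = [
    "ParameterError",
    "TorsionTerm",
    "ForceFieldParameters",
    "load_parameters",
    "serialize_parameters",
    "default_parameters",
    "largest_covalent_radius",
    "element_of_atom",
]

#: residue types with at least one scannable chi angle
SUPPORTED_RESIDUES = (
    "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)

ANY_COMP = "ANY"


class ParameterError(ValueError):
    """Raised for malformed or incomplete parameter files."""


@dataclass(frozen=True)
class TorsionTerm:
    """One cosine term (V/2)(1 + cos(n*chi - gamma)) of a torsion potential."""

    barrier: float          # V, kcal/mol
    periodicity: int        # n, must be a positive integer
    phase: float            # gamma, degrees

    def __post_init__(self):
        if self.periodicity <= 0 or int(self.periodicity) != self.periodicity:
            raise ParameterError(
                f"torsion periodicity must be a positive integer, got {self.periodicity}"
            )


def element_of_atom(atom_name: str) -> str:
    """Infer the element from a protein heavy-atom name (CA, OG1, SD, ...)."""
    name = atom_name.strip().upper()
    if name.startswith("SE"):
        return "SE"
    return name[0]


def _is_known_element(symbol: str) -> bool:
    el = gemmi.Element(symbol.capitalize())
    return el.atomic_number > 0


@dataclass
class ForceFieldParameters:
    """All physical parameters and weights used by scanning and scoring."""

    covalent_radius: dict[str, float] = field(default_factory=dict)
    covalent_radius_error: dict[str, float] = field(default_factory=dict)
    vdw_radius: dict[str, float] = field(default_factory=dict)
    lj_epsilon: dict[str, float] = field(default_factory=dict)
    lj_r_min: dict[str, float] = field(default_factory=dict)
    partial_charge: dict[tuple[str, str], float] = field(default_factory=dict)
    hbond_role: dict[tuple[str, str], str] = field(default_factory=dict)
    hbond_epsilon: float = 1.0
    hbond_r0: float = 2.9
    torsion: dict[str, list[TorsionTerm]] = field(default_factory=dict)
    w_lj: float = 1.0
    w_coulomb: float = 1.0
    w_hbond: float = 1.0
    w_torsion: float = 1.0
    cutoff_start: float = 2.5
    cutoff_end: float = 5.0
    bond_tolerance: float = 0.4
    bond_floor: float = 0.5
    dielectric: float = 1.0
    explicit_bonds: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    chi_defs: dict[str, list[tuple[str, str, str, str]]] = field(default_factory=dict)
    chi_bond_types: dict[str, list[str]] = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------

    def charge(self, comp_id: str, atom_name: str) -> float:
        q = self.partial_charge.get((comp_id, atom_name))
        if q is None:
            q = self.partial_charge.get((ANY_COMP, atom_name))
        if q is None:
            raise ParameterError(f"no partial charge for {comp_id}:{atom_name}")
        return q

    def has_charge(self, comp_id: str, atom_name: str) -> bool:
        return (comp_id, atom_name) in self.partial_charge or \
            (ANY_COMP, atom_name) in self.partial_charge

    def role(self, comp_id: str, atom_name: str) -> str | None:
        r = self.hbond_role.get((comp_id, atom_name))
        if r is None:
            r = self.hbond_role.get((ANY_COMP, atom_name))
        return r

    def lj(self, element: str) -> tuple[float, float]:
        el = element.upper()
        try:
            return self.lj_epsilon[el], self.lj_r_min[el]
        except KeyError:
            raise ParameterError(f"no Lennard-Jones parameters for element {element!r}")

    def torsion_terms(self, bond_type: str) -> list[TorsionTerm]:
        terms = self.torsion.get(self._torsion_key(bond_type))
        if not terms:
            raise ParameterError(f"no torsion terms for bond type {bond_type!r}")
        return terms

    @staticmethod
    def _torsion_key(bond_type: str) -> str:
        return "-".join(sorted(bond_type.upper().split("-")))

    def bonds_for(self, comp_id: str) -> list[tuple[str, str]]:
        """Intra-residue bond template: shared backbone bonds + side chain."""
        return list(self.explicit_bonds.get(ANY_COMP, [])) + \
            list(self.explicit_bonds.get(comp_id, []))

    def with_weights(self, w_lj=None, w_coulomb=None, w_hbond=None, w_torsion=None):
        """A copy with some term weights replaced (used by calibration)."""
        kw = {}
        if w_lj is not None:
            kw["w_lj"] = float(w_lj)
        if w_coulomb is not None:
            kw["w_coulomb"] = float(w_coulomb)
        if w_hbond is not None:
            kw["w_hbond"] = float(w_hbond)
        if w_torsion is not None:
            kw["w_torsion"] = float(w_torsion)
        return replace(self, **kw)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for table_name, table in (("covalent", self.covalent_radius),
                                  ("vdW", self.vdw_radius)):
            for el, r in table.items():
                if not _is_known_element(el):
                    raise ParameterError(f"unknown element symbol {el!r}")
                if not (r > 0):
                    raise ParameterError(f"{table_name} radius of {el} must be > 0")
        for el in list(self.lj_epsilon) + list(self.lj_r_min):
            if not _is_known_element(el):
                raise ParameterError(f"unknown element symbol {el!r}")
        if not (self.cutoff_end > self.cutoff_start > 0):
            raise ParameterError(
                f"need cutoff_end > cutoff_start > 0, got "
                f"({self.cutoff_start}, {self.cutoff_end})"
            )
        # every atom referenced by the residue templates must resolve to an
        # element with LJ parameters and to a partial charge
        for comp, bonds in self.explicit_bonds.items():
            if comp == ANY_COMP and not self.chi_defs:
                continue
            atoms = {a for bond in bonds for a in bond}
            if comp == ANY_COMP:
                atoms -= {"OXT"}  # optional terminal atom
            for atom in sorted(atoms):
                element = element_of_atom(atom)
                if element not in self.lj_epsilon:
                    raise ParameterError(
                        f"atom {comp}:{atom} has no Lennard-Jones entry for "
                        f"element {element!r}"
                    )
                lookup = ANY_COMP if comp == ANY_COMP else comp
                if not self.has_charge(lookup, atom):
                    raise ParameterError(f"atom {comp}:{atom} has no partial charge")


# -- parsing ---------------------------------------------------------------

_PREFIX = "rotascan"


def _block_floats(block, category: str, items: list[str]):
    rows = list(zip(*[block.find_loop(f"_{category}.{item}") for item in items]))
    return rows


def load_parameters(param_text: str) -> ForceFieldParameters:
    """Parse a parameter file; absent optional sections get defaults."""
    try:
        doc = gemmi.cif.read_string(param_text)
    except (RuntimeError, ValueError) as exc:
        raise ParameterError(f"cannot parse parameter file: {exc}") from exc
    if len(doc) == 0:
        raise ParameterError("parameter file contains no data block")
    block = doc[0]

    ff = ForceFieldParameters()

    def scalar(name, default, conv=float):
        raw = block.find_value(f"_{_PREFIX}_params.{name}")
        if raw is None:
            return default
        return conv(gemmi.cif.as_string(raw))

    ff.cutoff_start = scalar("cutoff_start", ff.cutoff_start)
    ff.cutoff_end = scalar("cutoff_end", ff.cutoff_end)
    ff.bond_tolerance = scalar("bond_tolerance", ff.bond_tolerance)
    ff.bond_floor = scalar("bond_floor", ff.bond_floor)
    ff.dielectric = scalar("dielectric", ff.dielectric)
    ff.hbond_epsilon = scalar("hbond_epsilon", ff.hbond_epsilon)
    ff.hbond_r0 = scalar("hbond_r0", ff.hbond_r0)
    ff.w_lj = scalar("weight_lj", 1.0)
    ff.w_coulomb = scalar("weight_coulomb", 1.0)
    ff.w_hbond = scalar("weight_hbond", 1.0)
    ff.w_torsion = scalar("weight_torsion", 1.0)

    for el, r, err in _block_floats(block, f"{_PREFIX}_covalent_radius",
                                    ["element", "radius", "error"]):
        ff.covalent_radius[el.upper()] = float(r)
        ff.covalent_radius_error[el.upper()] = float(err)
    for el, r in _block_floats(block, f"{_PREFIX}_vdw_radius",
                               ["element", "radius"]):
        ff.vdw_radius[el.upper()] = float(r)
    for el, eps, rmin in _block_floats(block, f"{_PREFIX}_lj",
                                       ["element", "epsilon", "r_min"]):
        ff.lj_epsilon[el.upper()] = float(eps)
        ff.lj_r_min[el.upper()] = float(rmin)
    for comp, atom, q in _block_floats(block, f"{_PREFIX}_charge",
                                       ["comp_id", "atom", "charge"]):
        ff.partial_charge[(comp, atom)] = float(q)
    for comp, atom, role in _block_floats(block, f"{_PREFIX}_hbond",
                                          ["comp_id", "atom", "role"]):
        if role not in ("donor", "acceptor", "both"):
            raise ParameterError(f"bad H-bond role {role!r} for {comp}:{atom}")
        ff.hbond_role[(comp, atom)] = role
    for bond, v, n, gamma in _block_floats(block, f"{_PREFIX}_torsion",
                                           ["bond", "barrier", "periodicity",
                                            "phase"]):
        key = ForceFieldParameters._torsion_key(bond)
        ff.torsion.setdefault(key, []).append(
            TorsionTerm(float(v), int(n), float(gamma)))
    for comp, idx, a1, a2, a3, a4, bond_type in _block_floats(
            block, f"{_PREFIX}_chi",
            ["comp_id", "index", "atom_1", "atom_2", "atom_3", "atom_4",
             "bond_type"]):
        defs = ff.chi_defs.setdefault(comp, [])
        if int(idx) != len(defs) + 1:
            raise ParameterError(f"chi definitions of {comp} are out of order")
        defs.append((a1, a2, a3, a4))
        ff.chi_bond_types.setdefault(comp, []).append(bond_type)
        ff.torsion_terms(bond_type)  # fail at load time if missing
    for comp, a1, a2 in _block_floats(block, f"{_PREFIX}_bond",
                                      ["comp_id", "atom_1", "atom_2"]):
        ff.explicit_bonds.setdefault(comp, []).append((a1, a2))

    ff.validate()
    return ff


def serialize_parameters(ff: ForceFieldParameters) -> str:
    """Write parameters back to CIF text; numeric round-trip is lossless."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("rotascan_parameters")
    p = f"_{_PREFIX}_params"
    for name, value in [
            ("cutoff_start", ff.cutoff_start), ("cutoff_end", ff.cutoff_end),
            ("bond_tolerance", ff.bond_tolerance), ("bond_floor", ff.bond_floor),
            ("dielectric", ff.dielectric),
            ("hbond_epsilon", ff.hbond_epsilon), ("hbond_r0", ff.hbond_r0),
            ("weight_lj", ff.w_lj), ("weight_coulomb", ff.w_coulomb),
            ("weight_hbond", ff.w_hbond), ("weight_torsion", ff.w_torsion)]:
        block.set_pair(f"{p}.{name}", repr(float(value)))

    def add_loop(category, tags, rows):
        if not rows:
            return
        loop = block.init_loop(f"_{_PREFIX}_{category}.", tags)
        for row in rows:
            loop.add_row([str(v) for v in row])

    add_loop("covalent_radius", ["element", "radius", "error"],
             [(el, repr(r), repr(ff.covalent_radius_error.get(el, 0.0)))
              for el, r in sorted(ff.covalent_radius.items())])
    add_loop("vdw_radius", ["element", "radius"],
             [(el, repr(r)) for el, r in sorted(ff.vdw_radius.items())])
    add_loop("lj", ["element", "epsilon", "r_min"],
             [(el, repr(ff.lj_epsilon[el]), repr(ff.lj_r_min[el]))
              for el in sorted(ff.lj_epsilon)])
    add_loop("charge", ["comp_id", "atom", "charge"],
             [(c, a, repr(q)) for (c, a), q in sorted(ff.partial_charge.items())])
    add_loop("hbond", ["comp_id", "atom", "role"],
             [(c, a, r) for (c, a), r in sorted(ff.hbond_role.items())])
    add_loop("torsion", ["bond", "barrier", "periodicity", "phase"],
             [(k, repr(t.barrier), t.periodicity, repr(t.phase))
              for k, terms in sorted(ff.torsion.items()) for t in terms])
    add_loop("chi", ["comp_id", "index", "atom_1", "atom_2", "atom_3", "atom_4",
                     "bond_type"],
             [(c, i + 1, *quad, ff.chi_bond_types[c][i])
              for c, defs in sorted(ff.chi_defs.items())
              for i, quad in enumerate(defs)])
    add_loop("bond", ["comp_id", "atom_1", "atom_2"],
             [(c, a1, a2) for c, bonds in sorted(ff.explicit_bonds.items())
              for a1, a2 in bonds])
    return doc.as_string()


_DEFAULT: ForceFieldParameters | None = None


def default_parameters() -> ForceFieldParameters:
    """The parameter set shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("rotascan.data").joinpath("parameters.cif").read_text()
        _DEFAULT = load_parameters(text)
    return _DEFAULT


def largest_covalent_radius(ff: ForceFieldParameters,
                            elements=None) -> float:
    """Largest covalent radius, optionally restricted to given elements."""
    table = ff.covalent_radius
    if elements is not None:
        table = {el: table[el] for el in {e.upper() for e in elements}
                 if el in table}
        missing = {e.upper() for e in elements} - set(table)
        if missing:
            raise ParameterError(
                f"elements missing from covalent radius table: {sorted(missing)}")
    if not table:
        raise ParameterError("covalent radius table is empty")
    return max(table.values())
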