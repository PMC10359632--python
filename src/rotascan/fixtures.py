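"""Synthetic ideal-geometry structures: residues, helices, clash scenarios.

The builders construct heavy-atom amino-acid geometry from internal
coordinates (bond length, bond angle, torsion) using natural-extension
reference frames, so every module of the package can be exercised without
downloading experimental structures.  Bond lengths and angles are standard
stereochemistry-table values (Engh/Huber-style averages) frozen in the
tables below; they are synthetic idealizations, not fitted to any
particular crystal structure.

What these fixtures emulate: connectivity, realistic bond geometry,
alpha-helical backbone environments and steric clashes.  What they do not
emulate: coordinate uncertainty of real experiments (see
``perturb_coordinates`` for isotropic noise), crystal contacts, solvent,
hydrogens and alternate conformations.
"""

from __future__ import annotations

import math

import numpy as np

from .forcefield import element_of_atom
from .mmcif_io import AtomSite, Structure, build_structure
from .topology import chi_definitions

__all__ = [
    "SUPPORTED_TYPES",
    "DEFAULT_CHI",
    "place_atom",
    "build_ideal_residue",
    "build_helix",
    "add_clash_probe",
    "perturb_coordinates",
    "ideal_arg_extension",
]

# -- ideal geometry tables ---------------------------------------------------

# backbone internal coordinates (lengths in angstroms, angles in degrees)
BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231, "ca_cb": 1.530,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "ang_n_ca_cb": 110.4, "ang_c_ca_cb": 110.5,
}

# side-chain atoms beyond CB:
#   atom: (ref_a, ref_b, ref_c, bond length, angle(ref_b, ref_c, atom),
#          torsion spec) where the torsion ref_a-ref_b-ref_c-atom is either
#   ("chi", i, offset_deg) or ("fix", deg).
SIDE_CHAIN: dict[str, list[tuple]] = {
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 114.4, ("chi", 1, 0.0))],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 120.0))],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0))],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 120.0))],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0))],
    "MET": [("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "SD", 1.791, 100.2, ("chi", 3, 0.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "CD", 1.520, 111.7, ("chi", 3, 0.0)),
            ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4, 0.0))],
    "ARG": [("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi", 3, 0.0)),
            ("CZ", "CG", "CD", "NE", 1.330, 124.2, ("chi", 4, 0.0)),
            ("NH1", "CD", "NE", "CZ", 1.326, 120.0, ("fix", 0.0)),
            ("NH2", "CD", "NE", "CZ", 1.326, 120.0, ("fix", 180.0))],
    "HIS": [("CG", "N", "CA", "CB", 1.504, 113.8, ("chi", 1, 0.0)),
            ("ND1", "CA", "CB", "CG", 1.378, 122.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.354, 131.2, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.320, 108.0, ("fix", 180.0)),
            ("NE2", "CB", "CG", "CD2", 1.374, 107.0, ("fix", 180.0))],
# PHE/TYR ring: CZ (and TYR OH) sit on the CB-CG line, the exact 2-fold
# axis of the ring, so a chi2 flip by 180 maps the ring onto itself under
# the CD1/CD2, CE1/CE2 label swap
    "PHE": [("CG", "N", "CA", "CB", 1.508, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.391, 120.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.391, 120.7, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.391, 120.0, ("fix", 180.0)),
            ("CE2", "CB", "CG", "CD2", 1.391, 120.0, ("fix", 180.0)),
            ("CZ", "CA", "CB", "CG", 2.782, 180.0, ("fix", 0.0))],
    "TYR": [("CG", "N", "CA", "CB", 1.508, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.391, 120.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.391, 120.7, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.391, 120.0, ("fix", 180.0)),
            ("CE2", "CB", "CG", "CD2", 1.391, 120.0, ("fix", 180.0)),
            ("CZ", "CA", "CB", "CG", 2.782, 180.0, ("fix", 0.0)),
            ("OH", "CA", "CG", "CZ", 1.376, 180.0, ("fix", 0.0))],
    "TRP": [("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.433, 126.6, ("chi", 2, 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.374, 110.2, ("fix", 180.0)),
            ("CE2", "CB", "CG", "CD2", 1.409, 107.2, ("fix", 180.0)),
            ("CE3", "CB", "CG", "CD2", 1.398, 133.9, ("fix", 0.0)),
            ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, ("fix", 180.0)),
            ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, ("fix", 180.0)),
            ("CH2", "CD2", "CE2", "CZ2", 1.368, 117.5, ("fix", 0.0))],
    "ALA": [],
    "GLY": [],
    "PRO": [("CG", "N", "CA", "CB", 1.492, 104.5, ("fix", 30.0)),
            ("CD", "CA", "CB", "CG", 1.503, 106.1, ("fix", -35.0))],
}

SUPPORTED_TYPES = tuple(sorted(set(SIDE_CHAIN) - {"ALA", "GLY", "PRO"}))

#: per-type default chi vector used when none is requested
DEFAULT_CHI = {comp: tuple([-60.0] + [180.0] * 3)[:_k] for comp, _k in {
    "ARG": 4, "ASN": 2, "ASP": 2, "CYS": 1, "GLN": 3, "GLU": 3, "HIS": 2,
    "ILE": 2, "LEU": 2, "LYS": 4, "MET": 3, "PHE": 2, "SER": 1, "THR": 1,
    "TRP": 2, "TYR": 2, "VAL": 1}.items()}
DEFAULT_CHI.update({"ALA": (), "GLY": (), "PRO": ()})


class FixtureError(ValueError):
    """Raised for unsupported residue types or invalid fixture requests."""


def place_atom(a, b, c, length: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Position a new atom D from three placed atoms via internal coordinates.

    ``length`` = |CD|, ``angle_deg`` = angle B-C-D, ``torsion_deg`` =
    dihedral A-B-C-D in the IUPAC sign convention of ``measure_dihedral``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise FixtureError("collinear reference atoms in place_atom")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(theta),
        length * math.sin(theta) * math.cos(tau),
        length * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n, ca, c) -> np.ndarray:
    """CB from the two backbone bond angles; the off-plane sign fixes L-chirality."""
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    u_n = (n - ca) / np.linalg.norm(n - ca)
    u_c = (c - ca) / np.linalg.norm(c - ca)
    cos_a = math.cos(math.radians(BB["ang_n_ca_cb"]))
    cos_b = math.cos(math.radians(BB["ang_c_ca_cb"]))
    dot = float(np.dot(u_n, u_c))
    # solve for the in-plane components p*u_n + q*u_c
    det = 1.0 - dot * dot
    p = (cos_a - cos_b * dot) / det
    q = (cos_b - cos_a * dot) / det
    in_plane = p * u_n + q * u_c
    s2 = 1.0 - float(np.dot(in_plane, in_plane))
    if s2 < 0:
        raise FixtureError("inconsistent CB bond angles")
    normal = np.cross(u_n, u_c)
    normal /= np.linalg.norm(normal)
    u = in_plane + math.sqrt(s2) * normal
    return ca + BB["ca_cb"] * u


def _residue_atoms(comp: str, backbone: dict[str, np.ndarray],
                   chi) -> dict[str, np.ndarray]:
    """All heavy atoms of one residue given its backbone and chi vector."""
    comp = comp.upper()
    if comp not in SIDE_CHAIN:
        raise FixtureError(f"unsupported residue type: {comp}")
    coords = dict(backbone)
    if comp != "GLY":
        coords["CB"] = _place_cb(coords["N"], coords["CA"], coords["C"])
    chi = tuple(float(c) for c in (chi if chi is not None else DEFAULT_CHI[comp]))
    expected = len(DEFAULT_CHI[comp])
    if len(chi) != expected:
        raise FixtureError(
            f"{comp} takes {expected} chi angles, got {len(chi)}")
    for name, ra, rb, rc, length, angle, tors in SIDE_CHAIN[comp]:
        kind = tors[0]
        if kind == "chi":
            tau = chi[tors[1] - 1] + tors[2]
        else:
            tau = tors[1]
        coords[name] = place_atom(coords[ra], coords[rb], coords[rc],
                                  length, angle, tau)
    return coords


_ATOM_ORDER_CACHE: dict[str, list[str]] = {}


def _atom_order(comp: str) -> list[str]:
    if comp not in _ATOM_ORDER_CACHE:
        order = ["N", "CA", "C", "O"]
        if comp != "GLY":
            order.append("CB")
        order += [row[0] for row in SIDE_CHAIN[comp]]
        _ATOM_ORDER_CACHE[comp] = order
    return _ATOM_ORDER_CACHE[comp]


def _to_structure(per_residue: list[tuple[str, int, dict]], asym="A") -> Structure:
    atoms = []
    atom_id = 0
    for comp, seq, coords in per_residue:
        for name in _atom_order(comp):
            atom_id += 1
            pos = coords[name]
            atoms.append(AtomSite(
                "ATOM", atom_id, element_of_atom(name), name, "", comp, asym,
                seq, float(pos[0]), float(pos[1]), float(pos[2]), 1))
    return build_structure(atoms)


def build_ideal_residue(residue_type: str, chi=None, phi: float | None = None,
                        psi: float = -47.0) -> Structure:
    """A single residue with ideal geometry and requested chi / psi angles.

    For an isolated residue phi is undefined (no preceding carbonyl); it is
    accepted for interface symmetry and ignored.  psi orients the carbonyl
    oxygen (dihedral N-CA-C-O = psi + 180).
    """
    comp = residue_type.upper()
    n = np.zeros(3)
    ca = np.array([BB["n_ca"], 0.0, 0.0])
    ang = math.radians(BB["ang_n_ca_c"])
    c = ca + BB["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    o = place_atom(n, ca, c, BB["c_o"], BB["ang_ca_c_o"], psi + 180.0)
    backbone = {"N": n, "CA": ca, "C": c, "O": o}
    coords = _residue_atoms(comp, backbone, chi)
    return _to_structure([(comp, 1, coords)])


def build_helix(sequence, phi: float = -57.0, psi: float = -47.0,
                chi=None) -> Structure:
    """An ideal alpha-helix (default phi=-57, psi=-47) with side chains.

    ``chi`` may be None (per-type defaults) or a list with one chi vector
    (or None) per residue.
    """
    sequence = [s.upper() for s in sequence]
    if not sequence:
        raise FixtureError("sequence must contain at least one residue")
    for comp in sequence:
        if comp not in SIDE_CHAIN:
            raise FixtureError(f"unsupported residue type: {comp}")
    if chi is None:
        chi = [None] * len(sequence)
    if len(chi) != len(sequence):
        raise FixtureError("need one chi vector (or None) per residue")

    # backbone trace
    n = np.zeros(3)
    ca = np.array([BB["n_ca"], 0.0, 0.0])
    ang = math.radians(BB["ang_n_ca_c"])
    c = ca + BB["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbones = [{"N": n, "CA": ca, "C": c}]
    for _ in sequence[1:]:
        prev = backbones[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"],
                            BB["c_n"], BB["ang_ca_c_n"], psi)
        ca_next = place_atom(prev["CA"], prev["C"], n_next,
                             BB["n_ca"], BB["ang_c_n_ca"], 180.0)  # omega
        c_next = place_atom(prev["C"], n_next, ca_next,
                            BB["ca_c"], BB["ang_n_ca_c"], phi)
        backbones.append({"N": n_next, "CA": ca_next, "C": c_next})
    for bb in backbones:
        bb["O"] = place_atom(bb["N"], bb["CA"], bb["C"],
                             BB["c_o"], BB["ang_ca_c_o"], psi + 180.0)

    per_residue = []
    for i, comp in enumerate(sequence):
        coords = _residue_atoms(comp, backbones[i], chi[i])
        per_residue.append((comp, i + 1, coords))
    return _to_structure(per_residue)


def add_clash_probe(structure: Structure, residue_key, chi,
                    offset: float = 0.0) -> Structure:
    """Copy of the structure with a carbon probe at the terminal-atom
    position the residue would occupy at the given chi vector.

    The probe guarantees a steric clash for that chi grid cell; a nonzero
    ``offset`` (angstroms, along +x) shifts it away.
    """
    from .kinematics import build_transform_chain

    new = structure.copy()
    residue = new.residue(tuple(residue_key))
    topo = chi_definitions(residue.comp_id)
    chain = build_transform_chain(residue.coords(), topo)
    coords = chain.evaluate(chi)
    # terminal atom: deepest level, placed last in build order
    terminal = [name for name, lv in topo.build_order
                if lv == max(l for _, l in topo.build_order)][-1]
    pos = coords[terminal] + np.array([float(offset), 0.0, 0.0])
    max_id = max(a.atom_id for a in new.atoms)
    probe = AtomSite("HETATM", max_id + 1, "C", "C1", "", "PRB", "Z",
                     1, float(pos[0]), float(pos[1]), float(pos[2]), 1)
    return build_structure(new.atoms + [probe])


def perturb_coordinates(structure: Structure, sigma: float,
                        seed: int = 0) -> Structure:
    """Isotropic Gaussian displacement of every atom (seeded)."""
    if sigma < 0:
        raise FixtureError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    new = structure.copy()
    if sigma > 0:
        for atom in new.atoms:
            atom.set_pos(atom.pos + rng.normal(0.0, sigma, size=3))
    return build_structure(new.atoms)


_ARG_EXTENSION: float | None = None


def ideal_arg_extension() -> float:
    """Max CA-to-side-chain-atom distance of ideal all-trans arginine."""
    global _ARG_EXTENSION
    if _ARG_EXTENSION is None:
        s = build_ideal_residue("ARG", chi=(180.0, 180.0, 180.0, 180.0))
        res = s.residues[0]
        ca = res.get_atom("CA").pos
        _ARG_EXTENSION = max(
            float(np.linalg.norm(a.pos - ca)) for a in res.atoms
            if a.atom_name not in ("N", "CA", "C", "O"))
    return _ARG_EXTENSION
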