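"""Pairwise energy model: Lennard-Jones, Coulomb, H-bond, torsion.

The total energy of a conformation is the weighted combination

    E_total = sum_pairs Q(r) * (w1*E_LJ + w2*E_C + w3*E_H) + sum_d w4*E_T(d)

with Q a smooth cosine switching function taking every nonbonded term
continuously to zero between ``cutoff_start`` and ``cutoff_end``.  Forms:

* LJ:      eps * [(r_min/r)^12 - 2 (r_min/r)^6]   (minimum -eps at r_min)
* Coulomb: k_e * q_a * q_b / (dielectric * r),  k_e = 332.0637 kcal*A/(mol*e^2)
* H-bond:  12-10 well D0 * [5 (r0/r)^12 - 6 (r0/r)^10] on donor/acceptor
  heavy-atom pairs (angle-independent)
* torsion: sum of cosine terms (V/2)(1 + cos(n*chi - gamma)); for the
  incremental scan the closed-form value of a rotated bond is distributed
  over its 1-4 atom pairs so partial sums stay consistent — the distributed
  parts sum exactly to the closed form.

Heavy atoms only by default (the shipped charges are united-atom style);
1-2 and 1-3 bonded pairs are excluded from the nonbonded sums and 1-4
pairs enter at full weight.  Sums use compensated (fsum) summation so the
totals are independent of pair ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forcefield import ForceFieldParameters

__all__ = [
    "EnergyError",
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "cutoff_factor",
    "lj_energy",
    "coulomb_energy",
    "hbond_energy",
    "is_hbond_pair",
    "nonbonded_terms",
    "pair_energy",
    "torsion_energy",
    "torsion_pair_parts",
    "total_energy",
]

#: k_e in kcal * angstrom / (mol * e^2)
COULOMB_CONSTANT = 332.0637


class EnergyError(ValueError):
    """Raised for unphysical inputs (coincident atoms, bad parameters)."""


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term sums plus their weighted total (all in kcal/mol)."""

    lj: float = 0.0
    coulomb: float = 0.0
    hbond: float = 0.0
    torsion: float = 0.0
    total: float = 0.0

    @staticmethod
    def combine(lj, coulomb, hbond, torsion, ff: ForceFieldParameters):
        total = math.fsum([ff.w_lj * lj, ff.w_coulomb * coulomb,
                           ff.w_hbond * hbond, ff.w_torsion * torsion])
        return EnergyBreakdown(lj, coulomb, hbond, torsion, total)


def cutoff_factor(r: float, start: float, end: float) -> float:
    """Cosine switching function: 1 below `start`, 0 above `end`."""
    if r <= start:
        return 1.0
    if r >= end:
        return 0.0
    return 0.5 * (1.0 + math.cos(math.pi * (r - start) / (end - start)))


def lj_energy(epsilon: float, r_min: float, r: float) -> float:
    x = (r_min / r) ** 6
    return epsilon * (x * x - 2.0 * x)


def coulomb_energy(q_a: float, q_b: float, r: float,
                   dielectric: float = 1.0) -> float:
    return COULOMB_CONSTANT * q_a * q_b / (dielectric * r)


def hbond_energy(depth: float, r0: float, r: float) -> float:
    """12-10 hydrogen-bond well with minimum -depth at r = r0."""
    x10 = (r0 / r) ** 10
    x12 = x10 * (r0 / r) ** 2
    return depth * (5.0 * x12 - 6.0 * x10)


def is_hbond_pair(role_a: str | None, role_b: str | None) -> bool:
    if role_a is None or role_b is None:
        return False
    return (role_a in ("donor", "both") and role_b in ("acceptor", "both")) \
        or (role_b in ("donor", "both") and role_a in ("acceptor", "both"))


def nonbonded_terms(element_a: str, q_a: float, role_a,
                    element_b: str, q_b: float, role_b,
                    r: float, ff: ForceFieldParameters
                    ) -> tuple[float, float, float]:
    """(LJ, Coulomb, H-bond) for one atom pair, cutoff factor applied."""
    if r <= 0.0:
        raise EnergyError("zero interatomic distance (duplicated atoms?)")
    if r >= ff.cutoff_end:
        return (0.0, 0.0, 0.0)
    q_factor = cutoff_factor(r, ff.cutoff_start, ff.cutoff_end)
    eps_a, rmin_a = ff.lj(element_a)
    eps_b, rmin_b = ff.lj(element_b)
    lj = lj_energy(math.sqrt(eps_a * eps_b), 0.5 * (rmin_a + rmin_b), r)
    coul = coulomb_energy(q_a, q_b, r, ff.dielectric)
    hb = hbond_energy(ff.hbond_epsilon, ff.hbond_r0, r) \
        if is_hbond_pair(role_a, role_b) else 0.0
    return (q_factor * lj, q_factor * coul, q_factor * hb)


def pair_energy(a, b, ff: ForceFieldParameters) -> tuple[float, float, float]:
    """Nonbonded triple for two AtomSite-like atoms (not 1-2/1-3 bonded)."""
    r = float(np.linalg.norm(a.pos - b.pos))
    return nonbonded_terms(
        a.element, ff.charge(a.comp_id, a.atom_name), ff.role(a.comp_id, a.atom_name),
        b.element, ff.charge(b.comp_id, b.atom_name), ff.role(b.comp_id, b.atom_name),
        r, ff)


def torsion_energy(chi_deg: float, terms) -> float:
    """Closed-form cosine torsion potential at one dihedral value."""
    if not terms:
        raise EnergyError("torsion term list is empty")
    chi = math.radians(chi_deg)
    return math.fsum(
        0.5 * t.barrier * (1.0 + math.cos(t.periodicity * chi
                                          - math.radians(t.phase)))
        for t in terms)


def torsion_pair_parts(total: float, n_pairs: int) -> list[float]:
    """Distribute a torsion value over its 1-4 pairs; parts sum exactly."""
    if n_pairs <= 0:
        raise EnergyError("torsion distribution needs at least one 1-4 pair")
    share = total / n_pairs
    parts = [share] * n_pairs
    parts[0] = total - math.fsum(parts[1:])
    return parts


def total_energy(pairs, torsions, ff: ForceFieldParameters) -> EnergyBreakdown:
    """Combine pair and torsion contributions into an energy breakdown.

    ``pairs`` is an iterable of (atom_a, atom_b) AtomSite-like pairs,
    ``torsions`` of (chi_deg, terms) tuples.  The result is deterministic
    under permutation of either list.
    """
    lj_vals, coul_vals, hb_vals = [], [], []
    for a, b in pairs:
        lj, coul, hb = pair_energy(a, b, ff)
        lj_vals.append(lj)
        coul_vals.append(coul)
        hb_vals.append(hb)
    torsion_vals = [torsion_energy(chi, terms) for chi, terms in torsions]
    # sort before compensated summation: permutation independence
    return EnergyBreakdown.combine(
        math.fsum(sorted(lj_vals)), math.fsum(sorted(coul_vals)),
        math.fsum(sorted(hb_vals)), math.fsum(sorted(torsion_vals)), ff)
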