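"""Analytic checks of the pairwise energy model."""

import math

import numpy as np
import pytest

from rotascan.energy import (COULOMB_CONSTANT, EnergyBreakdown, EnergyError,
                             coulomb_energy, cutoff_factor, hbond_energy,
                             is_hbond_pair, lj_energy, pair_energy,
                             torsion_energy, torsion_pair_parts,
                             total_energy)
from rotascan.forcefield import TorsionTerm
from rotascan.mmcif_io import AtomSite


def _atom(name, comp, element, pos, atom_id=1):
    return AtomSite("ATOM", atom_id, element, name, "", comp, "A", 1, *pos)


# -- switching function ------------------------------------------------------

@pytest.mark.parametrize("r,expected", [
    (2.5, 1.0), (5.0, 0.0), (3.75, 0.5), (1.0, 1.0), (8.0, 0.0),
])
def test_cutoff_factor_reference_points(r, expected):
    assert cutoff_factor(r, 2.5, 5.0) == pytest.approx(expected, abs=1e-12)


def test_cutoff_factor_monotone_and_smooth():
    rs = np.linspace(2.0, 5.5, 400)
    vals = [cutoff_factor(r, 2.5, 5.0) for r in rs]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    # continuity at both boundaries
    for r0 in (2.5, 5.0):
        assert abs(cutoff_factor(r0 - 1e-9, 2.5, 5.0)
                   - cutoff_factor(r0 + 1e-9, 2.5, 5.0)) < 1e-6


# -- pair terms ---------------------------------------------------------------

def test_lj_minimum_and_sigma_crossing():
    eps, rmin = 0.21, 3.4
    assert lj_energy(eps, rmin, rmin) == pytest.approx(-eps, abs=1e-12)
    sigma = rmin / 2 ** (1 / 6)
    assert lj_energy(eps, rmin, sigma) == pytest.approx(0.0, abs=1e-12)
    assert lj_energy(eps, rmin, 0.8 * sigma) > 0
    assert lj_energy(eps, rmin, 1.5 * rmin) < 0


def test_coulomb_closed_form():
    # q = +-0.5 e at 3 angstroms, dielectric 1
    expected = -COULOMB_CONSTANT * 0.25 / 3.0
    assert coulomb_energy(0.5, -0.5, 3.0) == pytest.approx(expected)


def test_hbond_12_10_minimum():
    assert hbond_energy(1.0, 2.9, 2.9) == pytest.approx(-1.0, abs=1e-12)
    assert hbond_energy(1.0, 2.9, 2.0) > 0


def test_hbond_pairing_rules():
    assert is_hbond_pair("donor", "acceptor")
    assert is_hbond_pair("acceptor", "both")
    assert not is_hbond_pair("donor", "donor")
    assert not is_hbond_pair("donor", None)
    assert not is_hbond_pair(None, None)


def test_pair_energy_zero_beyond_cutoff(ff):
    a = _atom("CB", "SER", "C", (0.0, 0.0, 0.0))
    b = _atom("CB", "LEU", "C", (ff.cutoff_end + 0.1, 0.0, 0.0), 2)
    assert pair_energy(a, b, ff) == (0.0, 0.0, 0.0)
    b.set_pos((ff.cutoff_end, 0.0, 0.0))
    assert pair_energy(a, b, ff) == (0.0, 0.0, 0.0)


def test_pair_energy_at_lj_minimum_inside_cutoff(ff):
    eps_c, rmin_c = ff.lj("C")
    # two carbons at exactly r_min, well inside cutoff_start would need
    # r_min < start; instead check against the switched analytic value
    a = _atom("CB", "SER", "C", (0.0, 0.0, 0.0))
    b = _atom("CB", "LEU", "C", (rmin_c, 0.0, 0.0), 2)
    lj, coul, hb = pair_energy(a, b, ff)
    q = cutoff_factor(rmin_c, ff.cutoff_start, ff.cutoff_end)
    assert lj == pytest.approx(-eps_c * q, rel=1e-12)
    assert hb == 0.0


def test_zero_distance_is_an_error(ff):
    a = _atom("CB", "SER", "C", (1.0, 2.0, 3.0))
    b = _atom("CB", "LEU", "C", (1.0, 2.0, 3.0), 2)
    with pytest.raises(EnergyError):
        pair_energy(a, b, ff)


def test_pair_energy_continuous_across_cutoff_boundaries(ff):
    """Sliding a pair through r = start and r = end shows no jump."""
    a = _atom("OG", "SER", "O", (0.0, 0.0, 0.0))
    b = _atom("O", "LEU", "O", (1.0, 0.0, 0.0), 2)
    for r0 in (ff.cutoff_start, ff.cutoff_end):
        values = []
        for r in (r0 - 1e-7, r0, r0 + 1e-7):
            b.set_pos((r, 0.0, 0.0))
            values.append(sum(pair_energy(a, b, ff)))
        # change across the boundary is slope-limited, not a jump
        assert abs(values[2] - values[0]) < 1e-4


# -- torsion ------------------------------------------------------------------

def test_torsion_cosine_values():
    terms = [TorsionTerm(1.0, 3, 0.0)]
    assert torsion_energy(60.0, terms) == pytest.approx(0.0, abs=1e-12)
    assert torsion_energy(0.0, terms) == pytest.approx(1.0, abs=1e-12)
    assert torsion_energy(120.0, terms) == pytest.approx(1.0, abs=1e-12)


def test_torsion_empty_terms_error():
    with pytest.raises(EnergyError):
        torsion_energy(0.0, [])


@pytest.mark.parametrize("n_pairs", [1, 2, 3, 9])
def test_torsion_parts_sum_exactly(n_pairs):
    total = torsion_energy(17.0, [TorsionTerm(1.4, 3, 0.0),
                                  TorsionTerm(0.5, 2, 180.0)])
    parts = torsion_pair_parts(total, n_pairs)
    assert len(parts) == n_pairs
    assert abs(math.fsum(parts) - total) < 1e-12


# -- totals -------------------------------------------------------------------

def _pair_fixture(ff):
    a = _atom("OG", "SER", "O", (0.0, 0.0, 0.0))
    b = _atom("O", "LEU", "O", (2.9, 0.0, 0.0), 2)
    return [(a, b)]


def test_total_zero_weights(ff):
    zero = ff.with_weights(0.0, 0.0, 0.0, 0.0)
    out = total_energy(_pair_fixture(ff), [(60.0, [TorsionTerm(1, 3, 0)])], zero)
    assert out.total == 0.0
    assert out.lj != 0.0   # term sums themselves are unweighted


def test_total_is_linear_in_weights(ff):
    pairs = _pair_fixture(ff)
    torsions = [(10.0, [TorsionTerm(1.0, 3, 0.0)])]
    base = total_energy(pairs, torsions, ff)
    double = total_energy(pairs, torsions, ff.with_weights(w_lj=2 * ff.w_lj))
    lhs = double.total - ff.w_coulomb * base.coulomb \
        - ff.w_hbond * base.hbond - ff.w_torsion * base.torsion
    rhs = 2 * (base.total - ff.w_coulomb * base.coulomb
               - ff.w_hbond * base.hbond - ff.w_torsion * base.torsion)
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_total_single_pair_equals_pair_energy(ff):
    pairs = _pair_fixture(ff)
    out = total_energy(pairs, [], ff)
    lj, coul, hb = pair_energy(*pairs[0], ff)
    assert (out.lj, out.coulomb, out.hbond) == (lj, coul, hb)
    assert out.total == pytest.approx(
        ff.w_lj * lj + ff.w_coulomb * coul + ff.w_hbond * hb, rel=1e-12)


def test_breakdown_combination_invariant(ff):
    out = EnergyBreakdown.combine(1.25, -0.5, -0.125, 0.75, ff)
    expected = ff.w_lj * 1.25 + ff.w_coulomb * -0.5 \
        + ff.w_hbond * -0.125 + ff.w_torsion * 0.75
    assert abs(out.total - expected) <= 1e-9 * max(1.0, abs(expected))


def test_total_independent_of_pair_order(ff, rng):
    atoms = [_atom(n, c, e, rng.uniform(0, 8, 3), i)
             for i, (n, c, e) in enumerate([
                 ("OG", "SER", "O"), ("O", "LEU", "O"), ("CB", "LEU", "C"),
                 ("NZ", "LYS", "N"), ("SD", "MET", "S"), ("CG", "ASP", "C")])]
    pairs = [(a, b) for i, a in enumerate(atoms) for b in atoms[i + 1:]]
    base = total_energy(pairs, [], ff).total
    for _ in range(10):
        rng.shuffle(pairs)
        shuffled = total_energy(pairs, [], ff).total
        assert abs(shuffled - base) <= 1e-9 * max(1.0, abs(base))


def test_energy_invariant_under_rigid_motion(ff, rng):
    """Global rotation + translation leaves every term unchanged."""
    atoms = [_atom(n, c, e, rng.uniform(0, 6, 3), i)
             for i, (n, c, e) in enumerate([
                 ("OG", "SER", "O"), ("O", "LEU", "O"), ("CB", "LEU", "C"),
                 ("NZ", "LYS", "N")])]
    pairs = [(a, b) for i, a in enumerate(atoms) for b in atoms[i + 1:]]
    base = total_energy(pairs, [], ff)

    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(-20, 20, 3)
    for atom in atoms:
        atom.set_pos(q @ atom.pos + shift)
    moved = total_energy(pairs, [], ff)
    for term in ("lj", "coulomb", "hbond", "total"):
        b, m = getattr(base, term), getattr(moved, term)
        assert abs(m - b) <= 1e-9 * max(1.0, abs(b))
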