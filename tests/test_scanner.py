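"""Environment selection, DEE grid scanning and rotamer acceptance."""

import numpy as np
import pytest

import oracles
from rotascan.energy import EnergyBreakdown
from rotascan.fixtures import (add_clash_probe, build_helix,
                               build_ideal_residue, ideal_arg_extension)
from rotascan.kinematics import wrap_angle
from rotascan.scanner import (GridScanSpec, RotamerRecord, ScanError,
                              accept_rotamers, dee_scan, generate_library,
                              reach_radius, select_environment)

SPEC30 = GridScanSpec(step=30.0, window=5.0)


def _accepted(structure, key, spec, ff, **kw):
    return accept_rotamers(dee_scan(structure, key, spec, ff, **kw),
                           spec.window)


# -- reach radius -------------------------------------------------------------

def test_reach_radius_formula(ff):
    expected = ideal_arg_extension() + 2 * max(ff.vdw_radius.values()) \
        + ff.cutoff_end
    assert reach_radius(ff) == pytest.approx(expected, abs=1e-12)
    assert reach_radius(ff) > 7.0


def test_reach_radius_linear_in_cutoff(ff):
    bumped = ff.with_weights()
    bumped.cutoff_end = ff.cutoff_end + 1.0
    assert reach_radius(bumped) - reach_radius(ff) == pytest.approx(1.0)


# -- environment selection ----------------------------------------------------

def test_isolated_residue_environment_is_own_backbone(ff):
    structure = build_ideal_residue("SER")
    env = select_environment(structure, ("A", 1, ""), reach_radius(ff), ff)
    assert sorted(a.atom_name for a in env) == ["C", "CA", "N", "O"]


def test_environment_matches_brute_force_on_large_helix(ff):
    helix = build_helix(["LEU", "GLN", "SER", "VAL", "THR"] * 10)
    key = ("A", 25, "")
    reach = reach_radius(ff)
    env = select_environment(helix, key, reach, ff)
    got = {id(a) for a in env}

    target = helix.residue(key)
    ca = target.get_atom("CA").pos
    want = {id(a) for a in target.atoms
            if a.atom_name in ("N", "CA", "C", "O", "OXT")}
    for res in helix.residues:
        if (res.asym_id, res.seq_id) == (key[0], key[1]):
            continue
        for a in res.atoms:
            if a.atom_name in ("N", "CA", "C", "O", "OXT", "CB") \
                    and np.linalg.norm(a.pos - ca) <= reach:
                want.add(id(a))
    assert got == want


def test_environment_never_contains_distal_side_chain_atoms(ff, helix10):
    env = select_environment(helix10, ("A", 5, ""), reach_radius(ff), ff)
    names = {a.atom_name for a in env if a.record_group == "ATOM"}
    assert names <= {"N", "CA", "C", "O", "OXT", "CB"}


def test_missing_ca_is_an_error(ff):
    structure = build_ideal_residue("SER")
    structure.atoms[:] = [a for a in structure.atoms if a.atom_name != "CA"]
    from rotascan.mmcif_io import build_structure
    broken = build_structure(structure.atoms)
    with pytest.raises(ScanError, match="CA"):
        select_environment(broken, ("A", 1, ""), reach_radius(ff), ff)


# -- grid geometry ------------------------------------------------------------

def test_spec_validation():
    with pytest.raises(ScanError):
        GridScanSpec(step=0.0)
    with pytest.raises(ScanError):
        GridScanSpec(step=7.0)        # does not divide 360
    with pytest.raises(ScanError):
        GridScanSpec(step=30.0, window=-1.0)


def test_half_range_grids():
    spec = GridScanSpec(step=30.0)
    assert spec.chi_grid("ASP", 2) == [-90.0, -60.0, -30.0, 0.0, 30.0, 60.0]
    assert len(spec.chi_grid("ASP", 1)) == 12
    assert len(spec.chi_grid("ASN", 2)) == 12   # amide O/N are distinct
    assert len(spec.chi_grid("GLN", 3)) == 12
    full = GridScanSpec(step=30.0, symmetry_reduce=False)
    assert len(full.chi_grid("ASP", 2)) == 12


# -- the scan itself ----------------------------------------------------------

def test_isolated_ser_large_window_keeps_all_grid_points(ff):
    structure = build_ideal_residue("SER", chi=(-60.0,))
    spec = GridScanSpec(step=30.0, window=1e6)
    accepted = _accepted(structure, ("A", 1, ""), spec, ff)
    assert sorted(r.chi[0] for r in accepted) == \
        [-180.0 + 30.0 * i for i in range(12)]


def test_clash_probe_removes_grid_cell(ff):
    structure = build_ideal_residue("SER", chi=(-60.0,))
    spec = GridScanSpec(step=30.0, window=1e6)
    probed = add_clash_probe(structure, ("A", 1, ""), (60.0,))
    accepted = _accepted(probed, ("A", 1, ""), spec, ff)
    assert 60.0 not in {r.chi[0] for r in accepted}
    far = add_clash_probe(structure, ("A", 1, ""), (60.0,), offset=10.0)
    accepted = _accepted(far, ("A", 1, ""), spec, ff)
    assert len(accepted) == 12


@pytest.mark.parametrize("key_seq,comp", [
    (4, "VAL"), (5, "THR"), (6, "CYS"),
])
def test_dee_equals_exhaustive_oracle_on_helix(ff, helix10, key_seq, comp):
    """Core oracle: pruning returns exactly the enumeration-accepted set."""
    key = ("A", key_seq, "")
    assert helix10.residue(key).comp_id == comp
    accepted = _accepted(helix10, key, SPEC30, ff)
    scan = oracles.exhaustive_scan(helix10, key, SPEC30, ff)
    want = oracles.accepted_set(scan, SPEC30.window)
    got = {r.chi: r.total for r in accepted}
    assert set(got) == set(want)
    for chi, total in got.items():
        assert abs(total - want[chi]) <= 1e-9 * max(1.0, abs(total))


def test_initial_conformation_survives_its_own_scan(ff):
    """An off-grid observed chi is evaluated and kept when within window."""
    structure = build_ideal_residue("SER", chi=(47.0,))
    spec = GridScanSpec(step=30.0, window=1e6)
    accepted = _accepted(structure, ("A", 1, ""), spec, ff)
    initial = [r for r in accepted if r.is_initial]
    assert len(initial) == 1
    assert initial[0].chi[0] == pytest.approx(47.0, abs=1e-6)
    assert len(accepted) == 13


def test_pruning_is_reported(ff, helix10):
    stats = {}
    dee_scan(helix10, ("A", 3, ""), SPEC30, ff, stats=stats)
    assert stats["pruned_branches"] > 0
    assert stats["leaves"] + stats["pruned_branches"] > 0


def test_half_range_scan_unfolds_onto_full_range(ff):
    """Symmetry-reduced ASP scan energy-matches the full-range scan."""
    structure = build_ideal_residue("ASP", chi=(-60.0, 40.0))
    key = ("A", 1, "")
    window = 10.0
    half = _accepted(structure, key,
                     GridScanSpec(step=30.0, window=window), ff)
    full = _accepted(structure, key,
                     GridScanSpec(step=30.0, window=window,
                                  symmetry_reduce=False), ff)
    half_map = {r.chi: r.total for r in half}
    for rec in full:
        c1, c2 = rec.chi
        folded = c2 if -90.0 <= c2 < 90.0 else wrap_angle(c2 + 180.0)
        assert (c1, folded) in half_map
        assert abs(half_map[(c1, folded)] - rec.total) <= \
            1e-9 * max(1.0, abs(rec.total))


# -- acceptance ---------------------------------------------------------------

def _records(energies):
    return [RotamerRecord(chi=(float(i),),
                          breakdown=EnergyBreakdown(total=e))
            for i, e in enumerate(energies)]


def test_accept_window_examples():
    kept = accept_rotamers(_records([0.0, 1.0, 10.0]), window=5.0)
    assert [r.total for r in kept] == [0.0, 1.0]
    assert all(r.accepted for r in kept)


def test_accept_all_equal_energies():
    kept = accept_rotamers(_records([2.0, 2.0, 2.0]), window=5.0)
    assert len(kept) == 3


def test_accept_window_zero_keeps_minimum_inclusively():
    kept = accept_rotamers(_records([3.0, 1.0, 1.0, 2.0]), window=0.0)
    assert [r.total for r in kept] == [1.0, 1.0]


def test_accept_empty_is_an_error():
    with pytest.raises(ScanError):
        accept_rotamers([], window=1.0)


def test_enlarging_window_never_removes_rotamers(ff, helix10):
    records = dee_scan(helix10, ("A", 7, ""),
                       GridScanSpec(step=30.0, window=20.0), ff)
    previous: set = set()
    for window in (0.0, 1.0, 3.0, 7.0, 15.0):
        kept = {r.chi for r in accept_rotamers(records, window)}
        assert previous <= kept
        previous = kept


def test_records_sorted_by_energy(ff, helix10):
    accepted = _accepted(helix10, ("A", 3, ""), SPEC30, ff)
    totals = [r.total for r in accepted]
    assert totals == sorted(totals)


# -- library assembly ---------------------------------------------------------

def test_generate_library_covers_scannable_residues(ff, helix10):
    lib = generate_library(helix10, spec=SPEC30, ff=ff)
    comps = {lib.comp_ids[k] for k in lib.entries}
    assert comps == {"SER", "LEU", "VAL", "THR", "CYS", "ASP", "MET"}
    for key, records in lib.entries.items():
        assert records, key
        assert all(r.accepted for r in records)
    assert lib.meta["pruned_branches"] > 0


def test_rotamer_coordinates_match_chain_evaluation(ff, helix10):
    """Stored coordinates equal a fresh kinematic evaluation at the chi."""
    from rotascan.kinematics import build_transform_chain
    from rotascan.topology import chi_definitions

    key = ("A", 4, "")
    accepted = _accepted(helix10, key, SPEC30, ff)
    residue = helix10.residue(key)
    chain = build_transform_chain(residue.coords(),
                                  chi_definitions(residue.comp_id, ff))
    for rec in accepted:
        fresh = chain.evaluate(rec.chi)
        for name, pos in fresh.items():
            assert np.linalg.norm(pos - rec.coords[name]) < 1e-9
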