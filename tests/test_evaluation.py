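"""Best-case RMSD / dihedral-angle metrics and symmetry handling."""

import math

import numpy as np
import pytest

import oracles
from rotascan.energy import EnergyBreakdown
from rotascan.evaluation import (ComparisonRecord, EvaluationError,
                                 bc_da, bc_rmsd, compare_library,
                                 flag_outliers, fold_difference,
                                 library_from_chi_table, report_tsv,
                                 rotamer_count, symmetry_rules)
from rotascan.fixtures import build_helix, build_ideal_residue
from rotascan.scanner import GridScanSpec, RotamerRecord, generate_library


def _candidate(comp, chi):
    res = build_ideal_residue(comp, chi=chi).residues[0]
    return RotamerRecord(chi=tuple(chi), breakdown=EnergyBreakdown(),
                         coords=res.coords(), accepted=True)


# -- symmetry rules -----------------------------------------------------------

def test_symmetry_rule_table():
    [asp] = symmetry_rules("ASP")
    assert (asp.chi_index, asp.scope) == (2, "always")
    assert asp.permutation == (("OD1", "OD2"),)
    assert symmetry_rules("LEU") == []
    [gln] = symmetry_rules("GLN")
    assert (gln.chi_index, gln.scope) == (3, "benchmarking")
    assert {r.comp_id for comp in ("ASP", "GLU", "PHE", "TYR")
            for r in symmetry_rules(comp) if r.scope == "always"} == \
        {"ASP", "GLU", "PHE", "TYR"}


def test_symmetry_rules_unknown_type_error():
    with pytest.raises(EvaluationError):
        symmetry_rules("PRO")
    with pytest.raises(EvaluationError):
        symmetry_rules("XYZ")


def test_permutation_is_involutive():
    for comp in ("ASP", "GLU", "PHE", "TYR", "ASN", "GLN"):
        for rule in symmetry_rules(comp):
            coords = build_ideal_residue(comp).residues[0].coords()
            twice = rule.permute(rule.permute(coords))
            assert set(twice) == set(coords)
            for name in coords:
                assert np.array_equal(twice[name], coords[name])


def test_permuted_conformation_measures_flipped_chi(ff):
    """Swapping ASP OD1/OD2 labels flips the measured chi2 by 180 degrees."""
    from rotascan.topology import chi_definitions
    res = build_ideal_residue("ASP", chi=(-60.0, 40.0)).residues[0]
    [rule] = symmetry_rules("ASP")
    permuted = rule.permute(res.coords())
    quad = chi_definitions("ASP", ff).chi_defs[1]
    chi2 = oracles.dihedral(*(permuted[n] for n in quad))
    assert math.remainder(chi2 - (40.0 + 180.0), 360.0) == \
        pytest.approx(0.0, abs=1e-6)


# -- bcRMSD -------------------------------------------------------------------

def test_identical_candidate_gives_zero():
    obs = build_ideal_residue("LEU", chi=(-60.0, 170.0)).residues[0]
    rmsd, idx = bc_rmsd(obs, [_candidate("LEU", (-60.0, 170.0))])
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert idx == 0


@pytest.mark.parametrize("comp,chi_obs,chi_flip", [
    ("ASP", (-60.0, 100.0), (-60.0, -80.0)),
    ("GLU", (-60.0, 180.0, 100.0), (-60.0, 180.0, -80.0)),
    ("PHE", (-60.0, 100.0), (-60.0, -80.0)),
    ("TYR", (-60.0, 100.0), (-60.0, -80.0)),
])
def test_symmetric_flip_is_zero_under_rules(comp, chi_obs, chi_flip):
    obs = build_ideal_residue(comp, chi=chi_obs).residues[0]
    cand = [_candidate(comp, chi_flip)]
    rules = symmetry_rules(comp)
    with_rules, _ = bc_rmsd(obs, cand, rules)
    without, _ = bc_rmsd(obs, cand, [])
    assert with_rules == pytest.approx(0.0, abs=1e-9)
    assert without > 0.5


def test_asn_gln_fold_is_benchmarking_only():
    obs = build_ideal_residue("ASN", chi=(-60.0, 100.0)).residues[0]
    cand = [_candidate("ASN", (-60.0, -80.0))]
    rules = symmetry_rules("ASN")
    normal, _ = bc_rmsd(obs, cand, rules, benchmarking=False)
    bench, _ = bc_rmsd(obs, cand, rules, benchmarking=True)
    assert bench < normal  # folding helps, though O/N geometry differs


def test_single_ser_candidate_matches_rodrigues_rmsd(ff):
    """bcRMSD of a 10-degree chi1 offset equals the axis-angle oracle."""
    from rotascan.topology import chi_definitions
    obs = build_ideal_residue("SER", chi=(50.0,)).residues[0]
    cand = _candidate("SER", (60.0,))
    rmsd, _ = bc_rmsd(obs, [cand])

    topo = chi_definitions("SER", ff)
    moved = oracles.side_chain_positions(obs.coords(), topo.chi_defs,
                                         topo.bonds, (60.0,))
    displacement = np.linalg.norm(moved["OG"] - obs.get_atom("OG").pos)
    # side chain = CB (identical) + OG: rmsd = |d_OG| / sqrt(2)
    assert rmsd == pytest.approx(displacement / math.sqrt(2.0), abs=1e-9)


def test_adding_candidates_never_increases_bcrmsd(rng):
    obs = build_ideal_residue("THR", chi=(-60.0,)).residues[0]
    candidates = []
    last = math.inf
    for chi in rng.uniform(-180.0, 180.0, size=8):
        candidates.append(_candidate("THR", (float(chi),)))
        rmsd, _ = bc_rmsd(obs, candidates)
        assert rmsd <= last + 1e-12
        last = rmsd


def test_mismatched_atom_names_error():
    obs = build_ideal_residue("SER").residues[0]
    with pytest.raises(EvaluationError):
        bc_rmsd(obs, [_candidate("THR", (-60.0,))])
    with pytest.raises(EvaluationError):
        bc_rmsd(obs, [])


# -- bcDA ---------------------------------------------------------------------

def test_bcda_identical_is_zero():
    obs = build_ideal_residue("LEU", chi=(-60.0, 170.0)).residues[0]
    da = bc_da(obs, [_candidate("LEU", (-60.0, 170.0))])
    assert np.allclose(da, 0.0, atol=1e-6)


def test_bcda_circular_wrap():
    obs = build_ideal_residue("SER", chi=(175.0,)).residues[0]
    da = bc_da(obs, [_candidate("SER", (-175.0,))])
    assert da[0] == pytest.approx(-10.0, abs=1e-6)


def test_bcda_symmetry_fold():
    obs = build_ideal_residue("ASP", chi=(-60.0, 100.0)).residues[0]
    da = bc_da(obs, [_candidate("ASP", (-60.0, -80.0))],
               symmetry_rules("ASP"))
    assert da[1] == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("delta,expected", [
    (0.0, 0.0), (170.0, -10.0), (-170.0, 10.0), (90.0, 90.0), (-90.0, 90.0),
    (250.0, 70.0),
])
def test_fold_difference(delta, expected):
    assert fold_difference(delta) == pytest.approx(expected)


# -- counts, outliers, reports --------------------------------------------------

def test_rotamer_count():
    entry = [_candidate("SER", (float(c),)) for c in range(12)]
    assert rotamer_count(entry) == 12
    entry[0].accepted = False
    assert rotamer_count(entry) == 11
    with pytest.raises(EvaluationError):
        rotamer_count(None)


@pytest.mark.parametrize("bcrmsd,bcda,rmsd_flag,angle_flag", [
    (0.05, (12.0,), False, False),       # below the RMSD threshold
    (0.25, (12.0, 3.0), True, True),
    (0.25, (5.0, 3.0), True, False),
    (0.10, (0.0,), True, False),         # boundary is inclusive
    (0.10, (10.0,), True, False),        # angle threshold is exclusive
    (0.10, (10.001,), True, True),
    (0.0999, (45.0,), False, False),     # angles only matter past the RMSD gate
])
def test_flag_outliers_threshold_table(bcrmsd, bcda, rmsd_flag, angle_flag):
    record = ComparisonRecord(("A", 1, ""), "SER", "lib", bcrmsd, bcda, 3)
    assert flag_outliers(record) == (rmsd_flag, angle_flag)


def test_self_comparison_of_generated_library_is_zero(ff, helix10):
    """Every scanned residue finds its own conformation in its library."""
    lib = generate_library(helix10, spec=GridScanSpec(step=30.0, window=1e6),
                           ff=ff)
    records = compare_library(helix10, lib)
    assert records
    for rec in records:
        assert rec.bcrmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rec.bcda, 0.0, atol=1e-6)
        assert not rec.rmsd_outlier


def test_chi_table_library_self_comparison(ff):
    """A chi table matching the observed angles reproduces the structure."""
    helix = build_helix(["SER", "VAL"], chi=[(-60.0,), (170.0,)])
    table = [("SER", -60.0), ("SER", 60.0), ("VAL", 170.0), ("VAL", -65.0)]
    lib = library_from_chi_table(helix, table, ff)
    assert set(lib.entries) == {("A", 1, ""), ("A", 2, "")}
    records = compare_library(helix, lib, library_name="table")
    for rec in records:
        assert rec.bcrmsd == pytest.approx(0.0, abs=1e-6)
        assert rec.count == 2


def test_report_tsv_layout(ff, helix10):
    lib = generate_library(helix10, keys=[("A", 2, "")],
                           spec=GridScanSpec(step=30.0), ff=ff)
    text = report_tsv(compare_library(helix10, lib))
    header, row = text.strip().split("\n")
    assert header.split("\t")[:6] == ["asym_id", "seq_id", "alt_loc",
                                      "comp_id", "library", "bcrmsd"]
    fields = row.split("\t")
    assert fields[3] == "SER"
    assert float(fields[5]) == pytest.approx(0.0, abs=1e-4)
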