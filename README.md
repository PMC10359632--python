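# rotascan

Structure-specific protein side-chain rotamer libraries.

Most rotamer libraries are statistical: they tabulate the most frequent
side-chain dihedral (χ) angles over a curated subset of the PDB, so they
average away conformations that are rare, strained, or forced by a
particular environment — exactly the ones that matter at active sites,
ligand pockets and protein–protein interfaces. `rotascan` takes the
opposite approach: given one structure, it *scans* each target side chain's
χ-angle space against that side chain's actual backbone surroundings,
scores every conformation with a pairwise physics energy, and keeps
everything below an energy window above the minimum. The result is a
rotamer library specific to the input protein, including sterically valid
but statistically rare conformations, and it works equally well for
residues (e.g. noncanonical amino acids) too rare in the PDB for
statistics.

## Method

**Kinematics.** Side-chain atom positions are generated from a χ vector by
chains of homogeneous 4×4 transforms

```
p' = T(n→0) · ∏ᵢ R(χᵢ) · T(i−1→i) · p
```

where each constant `T` aligns the rotated bond with a local Z axis and
`R(χᵢ)` is a Z rotation; constant segments are pre-multiplied once per
residue, so evaluating a grid point is a handful of small matrix products.
Rotations are rigid: internal bond lengths and angles are exact invariants.

**Energy.** Conformations are scored with

```
E_total = Σᵢ Σⱼ≠ᵢ Q(rᵢⱼ) · (w₁·E^LJ + w₂·E^C + w₃·E^H) + Σ_d w₄·E^T
```

a weighted sum of Lennard-Jones (ε[(r_min/r)¹² − 2(r_min/r)⁶]), Coulomb
(k_e·q_aq_b/r), and 12-10 hydrogen-bond terms under a smooth cosine
switching function `Q` that takes every nonbonded term continuously to zero
between 2.5 and 5 Å, plus cosine torsion terms (V/2)(1 + cos(nχ − γ)) per
rotated bond. All parameters (Pyykkö covalent radii, Amber-derived LJ and
charges, H-bond constants, torsions, weights w₁..w₄) live in one shipped
CIF-style parameter file and can be overridden.

**Search.** Interactions are computed between the moving side-chain atoms
and the mainchain (+CB) atoms within the reach radius of the target CA —
the all-trans arginine extension plus van der Waals radii plus the
interaction boundary — found with a cell-list ("cubing") grid. The χ grid
is explored depth-first with dead-end elimination: atoms are added level by
level, and a branch is pruned when its partial energy plus an admissible
best-possible-compensation bound exceeds the current pruning threshold.
The bound is a sum of precomputed per-pair potential minima, so the DEE
result is *identical* to exhaustive enumeration. For chemically symmetric
χ angles (ASP χ2, GLU χ3, PHE/TYR χ2) only the −90°…90° half range is
scanned. The observed input conformation is always evaluated as well, even
off-grid.

**Evaluation.** Libraries are compared to observed coordinates with
best-case RMSD (bcRMSD: minimum over rotamers and over symmetry-equivalent
atom relabelings, in the fixed structure frame, no superposition) and
best-case dihedral angles (bcDA: signed circular χ differences of the
bcRMSD-selected rotamer). Residues with bcRMSD ≥ 0.1 Å are flagged for
analysis, and among those, χ deviations above 10° are flagged as angle
outliers. The energy weights can be calibrated against reference
structures by particle swarm optimization of the mean bcRMSD.

## Worked example

Everything runs on synthetic ideal-geometry inputs, no downloads needed:

```sh
rotascan fixtures --kind helix --spec "ALA,SER,LEU,ALA" --out helix.cif
rotascan generate --input helix.cif --output library.cif --step 30
rotascan evaluate --input helix.cif --library library.cif --output report.tsv
```

The three commands print:

```
{"atoms": 24, "residues": 4}
{"residues_scanned": 2, "rotamers_accepted": 53, "branches_pruned": 102,
 "conformations_evaluated": 54, "step_deg": 30.0, "window": 5.0}
{"residues": 2, "rmsd_outliers": 0}
```

A 4-residue α-helix is built; its two scannable side chains (SER, LEU —
ALA has no χ angle) are scanned at a 30° step. SER keeps 6 of its 12 χ1
grid points within the 5 kcal/mol acceptance window; LEU keeps 47 of its
144 (χ1, χ2) cells; 102 of the 198 search branches were pruned by DEE
without changing the result. `report.tsv` then shows each residue finding
its own observed conformation in the library:

```
asym_id seq_id alt_loc comp_id library bcrmsd bcda_1 bcda_2 ... rotamer_count rmsd_outlier angle_outlier
A       2      .       SER     rotascan 0.0000 0.011  .     ... 6             0            0
A       3      .       LEU     rotascan 0.0000 0.000  -0.000 .. 47            0            0
```

bcRMSD is 0 within the file format's 3-decimal coordinate precision and no
residue is an outlier, as expected for a self-comparison. The library file
itself is PDBx/mmCIF: one `atom_site` model per rotamer plus a
`_rotascan_rotamer` loop with rank, χ angles (degrees) and the
LJ/Coulomb/H-bond/torsion/total energy breakdown per rotamer.

Other subcommands: `rotascan calibrate` (PSO weight fitting against
reference structures) and `rotascan fixtures --kind residue|helix|clash`
(synthetic test structures). `rotascan COMMAND --help` documents all flags.

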