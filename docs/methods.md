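# Methods

This note documents the model, the numerical choices and the deliberate
approximations behind `rotascan`, in the spirit of a package manual rather
than a results report. Every number quoted here is either a shipped
parameter or something the test suite / acceptance script computes.

## Model and assumptions

A rotamer library entry for one residue is the set of χ-grid conformations
whose total energy lies within an acceptance window ΔE above the
per-residue minimum. Three assumptions define the scope:

* **Rigid internal geometry.** Only χ dihedral angles move. Bond lengths,
  bond angles and ring internal geometry are fixed at their input values;
  bond-angle bending and bond-length variation are out of scope. Proline,
  whose conformational change requires exactly those degrees of freedom
  (ring puckering), is therefore not scanned; glycine and alanine have no
  χ angle. That leaves 17 supported residue types with 1–4 χ angles.
* **Rigid environment.** Each residue is scanned independently against the
  mainchain (N, CA, C, O, OXT) plus CB atoms of surrounding residues, all
  HETATM (ligand) atoms, and its own backbone. Side chains of other
  residues beyond CB are *not* part of the environment and pairs of
  flexible side chains are not co-packed; disulfide partners are treated
  as rigid. This is a deliberate design: libraries describe what the
  backbone permits, and side-chain-pairing decisions are left to the
  downstream packing application.
* **Heavy atoms only.** The shipped charges are united-atom-style values
  on heavy atoms; hydrogens are neither generated nor scored. The
  hydrogen bond is a distance-only 12-10 well on flagged donor/acceptor
  heavy-atom pairs.

## Energy function and parameters

`E_total = Σ_pairs Q(r)·(w₁E^LJ + w₂E^C + w₃E^H) + Σ_d w₄E^T` with

| term | form | defaults |
| --- | --- | --- |
| LJ | ε[(r_min/r)¹² − 2(r_min/r)⁶], arithmetic r_min / geometric ε combining | per-element ε, r_min (Amber-derived snapshot) |
| Coulomb | k_e q_a q_b / (D·r), k_e = 332.0637 kcal·Å/(mol·e²) | per-(residue, atom) charges; dielectric D = 1 |
| H-bond | D₀[5(r₀/r)¹² − 6(r₀/r)¹⁰] | D₀ = 1 kcal/mol, r₀ = 2.9 Å |
| switch Q | ½(1 + cos π(r−s)/(e−s)) between s and e | s = 2.5 Å, e = 5.0 Å |
| torsion | Σ (V/2)(1 + cos(nχ − γ)) per rotated bond | per bond class, see below |
| weights | w₁..w₄ | 1.0 each; fit by PSO if desired |

All of this lives in `src/rotascan/data/parameters.cif`, a single
self-describing CIF-style file also carrying Pyykkö covalent single-bond
radii (with uncertainties), van der Waals radii, per-residue bond
templates and the χ definitions. χ tables are data, not code, so users can
add noncanonical residue types (selenocysteine, pyrrolysine, ...) without
touching the source. `--parameters PATH` overrides the whole file.

Torsion terms are keyed by a bond *class* per χ (sp³–sp³ carbon 3-fold
V = 1.4; bonds into sp²/aromatic systems 2-fold; hydroxyl and thioether
3-fold with lower barriers). The 2-fold choice for sp³–sp² bonds is not
only chemically sensible — it is required for internal consistency: the
chemically 2-fold-symmetric χ angles (ASP χ2, GLU χ3, PHE/TYR χ2) must
have a 180°-periodic potential, otherwise the half-range scan and the
symmetry-folded evaluation would disagree with the full-range scan.

Units are nominally kcal/mol, but every decision the package makes uses
energy *differences* within one residue, so only relative scale matters
and the weights absorb units.

Exclusions: 1-2 and 1-3 bonded pairs are excluded from the nonbonded sums;
1-4 pairs enter at full weight (the torsion term is calibrated jointly).
For the scan's incremental accounting, the closed-form torsion value of a
rotated bond is distributed equally over its 1-4 atom pairs; the parts sum
to the closed form exactly (first part takes the fsum remainder), so
partial energies always add up to the total.

## Scan and dead-end elimination

The χ grid starts at −180° (or −90° for the symmetric half-range angles)
and steps upward; the default production step is 10°, the test suite and
calibration use 30° for speed. The measured input χ vector is always
evaluated as an extra off-grid point, so a sterically valid observed
conformation survives its own scan by construction. ASN χ2 and GLN χ3 are
always scanned over the full circle — their amide O/N atoms are chemically
distinct — and folded only at evaluation time, only when the benchmarking
flag is set.

DEE prunes a branch at level j when

```
E_partial(≤ j) + B(j) > E_best + ΔE + 1e-9
```

where B(j) is the sum, over every pair involving a not-yet-placed atom, of
the precomputed global minimum of that pair's weighted potential over
distance (searched on a 0.005 Å grid over [0.5 Å, cutoff_end], clipped to
≤ 0, lowered by a 0.01 safety slack against grid discretization; torsion
terms are bounded by zero since each cosine term is non-negative). The
bound is admissible, so pruning can only discard conformations no window
could accept: the accepted set equals exhaustive enumeration exactly, which
the test suite asserts pair-for-pair at 1e-9.

Distances below 0.05 Å in the scan path are clamped to 0.05 Å — a vast but
finite LJ repulsion — so a probe atom placed exactly on a rotamer position
rejects that grid cell instead of raising. The strict `pair_energy` API
still treats r = 0 as an error (duplicated atoms).

Energy sums use compensated (`math.fsum`) summation over sorted term lists,
making totals independent of pair ordering; ties in the final energy sort
break on the χ tuple, so library files are byte-stable across runs.

## Evaluation conventions

* bcRMSD is computed over side-chain heavy atoms (CB outward) in the fixed
  structure frame with **no superposition** — candidates are built on the
  observed backbone, and superposition would hide exactly the displacement
  a modeller cares about. RMSD conventions vary between tools; this one is
  deliberate and load-bearing.
* Symmetry rules fold ASP χ2 (OD1↔OD2), GLU χ3 (OE1↔OE2) and PHE/TYR χ2
  (CD1↔CD2, CE1↔CE2) always; ASN χ2 (OD1↔ND2) and GLN χ3 (OE1↔NE2) only
  under the benchmarking flag, and since C=O and C–N geometry genuinely
  differ, their folded bcRMSD is reduced but not zero.
* bcDA is observed − predicted, wrapped into (−180°, 180°]; symmetric χ
  differences are folded into (−90°, 90°].
* Outlier flags: bcRMSD ≥ 0.1 Å (inclusive); angle outlier requires the
  RMSD flag plus some |bcDA| strictly > 10°. The 0.1 Å / 10° thresholds
  are analysis conventions, not geometric identities.
* External χ tables (whitespace columns: type, χ1..χk[, weight]) are
  realized onto the observed backbone through the residue's own transform
  chain, i.e. with the residue's internal geometry; only the dihedral
  angles are imposed. A backbone-dependent table should be pre-filtered to
  the relevant ϕ/ψ bin by the caller.

## Calibration

`pso_fit` is a global-best particle swarm with inertia 0.72 and
cognitive = social = 1.49 (standard constriction-equivalent values),
positions clamped to bounds, one seeded generator for the whole run, and
the per-iteration best trace recorded (non-increasing by construction).
The objective regenerates libraries under candidate weights at a coarse
30° step with a zero acceptance window and returns the mean bcRMSD over
reference residues — a deliberately cheap, deliberately discrete
objective. Two caveats are inherent and documented rather than hidden:
the objective is piecewise constant (a plateau per energy-ordering), and
the weights are identifiable only up to ratios that preserve those
orderings, so recovery is asserted on the objective value, not on the raw
weight vector.

## Synthetic data

`rotascan.fixtures` builds ideal-geometry residues, α-helices (ϕ = −57°,
ψ = −47°, ω = 180°), clash probes and Gaussian coordinate noise from
frozen stereochemistry-table values (Engh/Huber-style averages; see the
module header). The PHE/TYR ring places CZ (and OH) on the CB–CG line —
the exact 2-fold axis — so the χ2 flip symmetry is exact to rounding, and
the ASP/ASN/GLU/GLN branch atoms use identical lengths/angles per branch
for the same reason. These fixtures emulate connectivity, realistic bond
geometry, helical backbone environments and steric clashes. They do not
emulate experimental coordinate error (beyond optional isotropic noise),
crystal contacts, solvent, hydrogens, or the conformational diversity of
real proteins — so green tests demonstrate algorithmic correctness
(kinematics, search exactness, symmetry handling, thresholds), not
predictive accuracy on experimental structures.

## Problem sizes

The default test suite scans k ≤ 2 residues at 30° (seconds per residue);
the acceptance script scans a 17-residue mixed helix at the production 10°
step with CYS/SER/VAL/THR/LEU/ASP/ASN/MET targets, relaxing each side
chain to its minimum-energy rotamer first so the self-evaluation metric is
a clean zero. LYS/ARG at 10° are exact but take minutes per residue in
pure Python, so the script's full-depth demonstrations use the shorter
types and covers the 4-χ chains through the kinematics and coarser-step
oracle comparisons instead. The PSO demonstrations use a 30-particle /
200-iteration sphere benchmark and a 16-particle / 20-iteration weight
recovery on four hydrophobic reference residues (VAL/LEU/CYS/ILE), chosen
because their energy orderings are stable over a wide weight region,
making the recovery target well-posed despite the scale degeneracy.

## Known limitations

* No multi-residue packing, ligand flexibility, or continuous χ
  optimization between grid points.
* No solvation, polarization or entropy terms; the H-bond term is
  angle-independent.
* The shipped parameter snapshot is a reproducible default, not a tuned
  force field; for production use the weights (and torsions) should be
  calibrated against structures of interest.
* Scanning cost grows as (360/step)^k; 4-χ residues at fine steps are
  expensive in this pure-Python implementation.
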