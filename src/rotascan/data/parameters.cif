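# Default rotascan force-field parameter file.
#
# Covalent single-bond radii follow Pyykko's self-consistent set.
# Lennard-Jones well depths / minimum distances and partial charges are an
# Amber-derived per-element / per-atom snapshot frozen here so that runs are
# reproducible without external files.  Hydrogen-bond donors and acceptors
# are flagged on heavy atoms and scored with a 12-10 well.  Energies are in
# kcal/mol, distances in angstroms, angles in degrees, charges in units of
# the elementary charge.
data_rotascan_parameters

_rotascan_params.cutoff_start     2.5
_rotascan_params.cutoff_end       5.0
_rotascan_params.bond_tolerance   0.4
_rotascan_params.bond_floor       0.5
_rotascan_params.dielectric       1.0
_rotascan_params.hbond_epsilon    1.0
_rotascan_params.hbond_r0         2.9
_rotascan_params.weight_lj        1.0
_rotascan_params.weight_coulomb   1.0
_rotascan_params.weight_hbond     1.0
_rotascan_params.weight_torsion   1.0

loop_
_rotascan_covalent_radius.element
_rotascan_covalent_radius.radius
_rotascan_covalent_radius.error
H  0.32 0.02
C  0.75 0.03
N  0.71 0.02
O  0.63 0.02
P  1.11 0.03
S  1.03 0.03
SE 1.16 0.04

loop_
_rotascan_vdw_radius.element
_rotascan_vdw_radius.radius
H  1.20
C  1.70
N  1.55
O  1.52
P  1.80
S  1.80
SE 1.90

loop_
_rotascan_lj.element
_rotascan_lj.epsilon
_rotascan_lj.r_min
H  0.0157 2.000
C  0.1094 3.816
N  0.1700 3.648
O  0.2100 3.322
P  0.2000 4.200
S  0.2500 4.000
SE 0.3000 4.200

# Backbone charges apply to every residue type (comp_id "ANY"); a
# residue-specific row overrides the ANY row.
loop_
_rotascan_charge.comp_id
_rotascan_charge.atom
_rotascan_charge.charge
ANY N    -0.416
ANY CA    0.035
ANY C     0.597
ANY O    -0.567
ANY OXT  -0.800
ALA CB    0.040
ARG CB    0.000
ARG CG    0.020
ARG CD    0.090
ARG NE   -0.230
ARG CZ    0.760
ARG NH1  -0.100
ARG NH2  -0.100
ASN CB   -0.080
ASN CG    0.680
ASN OD1  -0.600
ASN ND2  -0.450
ASP CB   -0.100
ASP CG    0.750
ASP OD1  -0.750
ASP OD2  -0.750
CYS CB    0.100
CYS SG   -0.180
GLN CB   -0.020
GLN CG   -0.060
GLN CD    0.680
GLN OE1  -0.600
GLN NE2  -0.450
GLU CB    0.000
GLU CG   -0.100
GLU CD    0.750
GLU OE1  -0.750
GLU OE2  -0.750
HIS CB   -0.030
HIS CG    0.180
HIS ND1  -0.250
HIS CD2  -0.220
HIS CE1   0.160
HIS NE2  -0.280
ILE CB    0.070
ILE CG1   0.020
ILE CG2  -0.060
ILE CD1  -0.070
LEU CB    0.020
LEU CG    0.100
LEU CD1  -0.070
LEU CD2  -0.070
LYS CB    0.000
LYS CG    0.010
LYS CD    0.030
LYS CE    0.200
LYS NZ    0.300
MET CB    0.030
MET CG    0.020
MET SD   -0.270
MET CE    0.020
PHE CB   -0.030
PHE CG    0.010
PHE CD1  -0.080
PHE CD2  -0.080
PHE CE1  -0.080
PHE CE2  -0.080
PHE CZ   -0.080
PRO CB   -0.010
PRO CG    0.020
PRO CD    0.040
SER CB    0.210
SER OG   -0.400
THR CB    0.270
THR OG1  -0.400
THR CG2  -0.050
TRP CB   -0.010
TRP CG   -0.100
TRP CD1   0.040
TRP CD2   0.120
TRP NE1  -0.350
TRP CE2   0.160
TRP CE3  -0.100
TRP CZ2  -0.100
TRP CZ3  -0.100
TRP CH2  -0.100
TYR CB   -0.030
TYR CG    0.010
TYR CD1  -0.080
TYR CD2  -0.080
TYR CE1  -0.080
TYR CE2  -0.080
TYR CZ    0.320
TYR OH   -0.450
VAL CB    0.050
VAL CG1  -0.060
VAL CG2  -0.060

# Hydrogen-bond roles on heavy atoms: donor, acceptor or both.
loop_
_rotascan_hbond.comp_id
_rotascan_hbond.atom
_rotascan_hbond.role
ANY N    donor
ANY O    acceptor
ANY OXT  acceptor
ARG NE   donor
ARG NH1  donor
ARG NH2  donor
ASN OD1  acceptor
ASN ND2  donor
ASP OD1  acceptor
ASP OD2  acceptor
GLN OE1  acceptor
GLN NE2  donor
GLU OE1  acceptor
GLU OE2  acceptor
HIS ND1  both
HIS NE2  both
LYS NZ   donor
MET SD   acceptor
SER OG   both
THR OG1  both
TRP NE1  donor
TYR OH   both

# Torsional terms keyed by the class of the central (rotated) bond:
# CT sp3 carbon, C2 sp2/aromatic carbon, OH hydroxyl oxygen, S sulfur,
# N3 sp3 (ammonium) nitrogen, N2 sp2 (guanidinium/amide) nitrogen.
# E(chi) = sum over terms of (V/2) * (1 + cos(n*chi - gamma)).
# Bonds into sp2 systems use 2-fold terms, so the potential shares the
# 180-degree periodicity of the chemically symmetric chi angles.
loop_
_rotascan_torsion.bond
_rotascan_torsion.barrier
_rotascan_torsion.periodicity
_rotascan_torsion.phase
CT-CT 1.40 3 0.0
CT-C2 0.50 2 180.0
CT-OH 0.50 3 0.0
CT-S  1.00 3 0.0
CT-N3 1.40 3 0.0
CT-N2 0.50 3 0.0
N2-C2 1.80 2 180.0

# Chi dihedral definitions (IUPAC atom quadruples), one row per chi,
# with the torsion class of the rotated (atom_2 - atom_3) bond.
loop_
_rotascan_chi.comp_id
_rotascan_chi.index
_rotascan_chi.atom_1
_rotascan_chi.atom_2
_rotascan_chi.atom_3
_rotascan_chi.atom_4
_rotascan_chi.bond_type
ARG 1 N  CA CB  CG  CT-CT
ARG 2 CA CB CG  CD  CT-CT
ARG 3 CB CG CD  NE  CT-N2
ARG 4 CG CD NE  CZ  N2-C2
ASN 1 N  CA CB  CG  CT-CT
ASN 2 CA CB CG  OD1 CT-C2
ASP 1 N  CA CB  CG  CT-CT
ASP 2 CA CB CG  OD1 CT-C2
CYS 1 N  CA CB  SG  CT-S
GLN 1 N  CA CB  CG  CT-CT
GLN 2 CA CB CG  CD  CT-CT
GLN 3 CB CG CD  OE1 CT-C2
GLU 1 N  CA CB  CG  CT-CT
GLU 2 CA CB CG  CD  CT-CT
GLU 3 CB CG CD  OE1 CT-C2
HIS 1 N  CA CB  CG  CT-CT
HIS 2 CA CB CG  ND1 CT-C2
ILE 1 N  CA CB  CG1 CT-CT
ILE 2 CA CB CG1 CD1 CT-CT
LEU 1 N  CA CB  CG  CT-CT
LEU 2 CA CB CG  CD1 CT-CT
LYS 1 N  CA CB  CG  CT-CT
LYS 2 CA CB CG  CD  CT-CT
LYS 3 CB CG CD  CE  CT-CT
LYS 4 CG CD CE  NZ  CT-N3
MET 1 N  CA CB  CG  CT-CT
MET 2 CA CB CG  SD  CT-S
MET 3 CB CG SD  CE  CT-S
PHE 1 N  CA CB  CG  CT-CT
PHE 2 CA CB CG  CD1 CT-C2
SER 1 N  CA CB  OG  CT-OH
THR 1 N  CA CB  OG1 CT-OH
TRP 1 N  CA CB  CG  CT-CT
TRP 2 CA CB CG  CD1 CT-C2
TYR 1 N  CA CB  CG  CT-CT
TYR 2 CA CB CG  CD1 CT-C2
VAL 1 N  CA CB  CG1 CT-CT

# Explicit intra-residue bond templates.  "ANY" rows are backbone bonds
# shared by all residue types; peptide and disulfide links are found by the
# geometric (cell-grid) fallback.
loop_
_rotascan_bond.comp_id
_rotascan_bond.atom_1
_rotascan_bond.atom_2
ANY N   CA
ANY CA  C
ANY C   O
ANY C   OXT
ALA CA  CB
ARG CA  CB
ARG CB  CG
ARG CG  CD
ARG CD  NE
ARG NE  CZ
ARG CZ  NH1
ARG CZ  NH2
ASN CA  CB
ASN CB  CG
ASN CG  OD1
ASN CG  ND2
ASP CA  CB
ASP CB  CG
ASP CG  OD1
ASP CG  OD2
CYS CA  CB
CYS CB  SG
GLN CA  CB
GLN CB  CG
GLN CG  CD
GLN CD  OE1
GLN CD  NE2
GLU CA  CB
GLU CB  CG
GLU CG  CD
GLU CD  OE1
GLU CD  OE2
HIS CA  CB
HIS CB  CG
HIS CG  ND1
HIS CG  CD2
HIS ND1 CE1
HIS CD2 NE2
HIS CE1 NE2
ILE CA  CB
ILE CB  CG1
ILE CB  CG2
ILE CG1 CD1
LEU CA  CB
LEU CB  CG
LEU CG  CD1
LEU CG  CD2
LYS CA  CB
LYS CB  CG
LYS CG  CD
LYS CD  CE
LYS CE  NZ
MET CA  CB
MET CB  CG
MET CG  SD
MET SD  CE
PHE CA  CB
PHE CB  CG
PHE CG  CD1
PHE CG  CD2
PHE CD1 CE1
PHE CD2 CE2
PHE CE1 CZ
PHE CE2 CZ
PRO CA  CB
PRO CB  CG
PRO CG  CD
PRO CD  N
SER CA  CB
SER CB  OG
THR CA  CB
THR CB  OG1
THR CB  CG2
TRP CA  CB
TRP CB  CG
TRP CG  CD1
TRP CG  CD2
TRP CD1 NE1
TRP NE1 CE2
TRP CD2 CE2
TRP CD2 CE3
TRP CE2 CZ2
TRP CE3 CZ3
TRP CZ2 CH2
TRP CZ3 CH2
TYR CA  CB
TYR CB  CG
TYR CG  CD1
TYR CG  CD2
TYR CD1 CE1
TYR CD2 CE2
TYR CE1 CZ
TYR CE2 CZ
TYR CZ  OH
VAL CA  CB
VAL CB  CG1
VAL CB  CG2
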