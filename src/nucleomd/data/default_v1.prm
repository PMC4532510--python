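# nucleomd force-field parameter file, schema version 1
#
# Units: energy kcal/mol, length Angstrom, angle radian unless a key says _deg,
# mass g/mol, charge in elementary charges.
# Sections are [name]; entries are "key = value"; '#' starts a comment.
# Every coefficient used by the energy evaluators lives here; evaluation code
# carries no numeric force-field constants.

[meta]
schema_version = 1
name = nucleomd-default

[protein]
# Calpha structure-based (Go) chain: harmonic bonds/angles, 1+3 cosine dihedrals,
# 12-10 native contacts, r^-12 excluded volume.
k_bond = 100.0          # kcal/mol/A^2
k_angle = 20.0          # kcal/mol/rad^2
k_dihedral_1 = 1.0      # kcal/mol
k_dihedral_3 = 0.5      # kcal/mol
eps_go = 0.3            # kcal/mol per native contact
eps_ev = 0.2            # kcal/mol
sigma_ev = 4.0          # A
ev_cutoff_factor = 3.2  # excluded volume truncated at factor * sigma_ev

[dna]
# Three-site-per-nucleotide model: quadratic+quartic bonds, harmonic angles
# (with the 1/2 prefactor), single-cosine dihedrals, 12-6 stacking at native
# distance, 12-10 base pairing, truncated-shifted (WCA) excluded volume,
# screened Coulomb on phosphates, Morse-like solvation assisting base pairing.
k_bond_2 = 0.6          # kcal/mol/A^2   (quadratic)
k_bond_4 = 60.0         # kcal/mol/A^4   (quartic)
k_angle = 40.0          # kcal/mol/rad^2 (V = k/2 (theta-theta0)^2)
k_dihedral = 2.0        # kcal/mol
eps_stack = 0.5         # kcal/mol
eps_bp_AT = 1.8         # kcal/mol
eps_bp_GC = 2.7         # kcal/mol  (three H-bonds vs two: 3:2 ratio)
sigma_bp_AT = 6.06218   # A, paired base-base site distance in the ideal helix
sigma_bp_GC = 6.06218   # A
eps_ev = 0.2            # kcal/mol
sigma_ev = 2.5          # A; must stay below the closest cross-strand site
                        # separation of strongly bent duplexes (backbone
                        # overlap is prevented mainly by phosphate repulsion)
eps_solv = 0.5          # kcal/mol
alpha_solv = 1.0        # 1/A
r_solv = 7.6361         # A, cross-strand diagonal base-base distance, ideal helix

[pro_dna]
# Protein-DNA coupling: 12-10 native contacts to sugar/base sites only,
# scaled from the protein contact strength; r^-12 excluded volume; screened
# Coulomb shared with the electrostatics section.
go_scaling = 0.8        # eps_go_pro_dna = go_scaling * protein eps_go
eps_ev = 0.2            # kcal/mol
sigma_ev = 4.5          # A
ev_cutoff_factor = 3.2

[electrostatics]
dielectric = 78.0       # relative permittivity of water, fixed
cutoff_debye_multiple = 5.0   # screened Coulomb truncated at this * lambda_D

[contacts]
# Native-contact definition policy: CG-site distance threshold, applied
# identically to protein-protein and protein-DNA pairs.
cutoff = 6.5            # A
min_sequence_separation = 4   # protein pairs require |i-j| > 3

[dna_geometry]
# Ideal B-form helix used for fixture construction and for the reference
# values of all DNA bonded and stacking terms. Cylindrical site placement
# per base-pair frame; the complementary strand is the dyad image (y -> -y,
# local z -> -z) rotated by the groove-asymmetry offset below.
strand2_azimuth_offset_deg = -40.0
rise = 3.38             # A per bp
twist_deg = 36.0        # per bp
phosphate_radius = 8.9
phosphate_azimuth_deg = -18.0
phosphate_z = -1.69
sugar_radius = 6.9
sugar_azimuth_deg = 0.0
sugar_z = 0.0
base_radius = 3.5
base_azimuth_deg = 40.0
base_z = 0.0

[masses]
# CG site masses, g/mol. Protein beads carry the residue mass; DNA sites the
# chemical-group mass (phosphate, deoxyribose, base).
ALA = 71.08
ARG = 156.19
ASN = 114.10
ASP = 115.09
CYS = 103.14
GLN = 128.13
GLU = 129.12
GLY = 57.05
HIS = 137.14
ILE = 113.16
LEU = 113.16
LYS = 128.17
MET = 131.19
PHE = 147.18
PRO = 97.12
SER = 87.08
THR = 101.10
TRP = 186.21
TYR = 163.18
VAL = 99.13
DP = 94.97
DS = 99.11
DA = 134.12
DG = 150.13
DC = 110.09
DT = 125.11
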