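# Default pocket definitions for the homopentameric alpha1 glycine receptor
# extracellular domain (author numbering of the 6PM5 cryo-EM structure).
#
# Each of the five interfacial pockets is bordered by 7 binding residues on
# the principal (+) subunit and 4 on the complementary (-) subunit.  The
# Loop C orientation angle is measured at the hinge (O) between rays to the
# apex (C) and to a complementary-side reference point (G), each point being
# the Calpha centroid of a residue pair.

ring_reversed: false
occupied_pockets: all

principal_binding_residues:
  - PHE115
  - GLU173
  - SER174
  - PHE175
  - TYR218
  - THR220
  - PHE223

complementary_binding_residues:
  - PHE79
  - ARG81
  - LEU133
  - SER145

loopc_apex_pair: [ASN219, THR220]
loopc_hinge_pair: [THR215, THR224]
complementary_reference_pair: [ASN58, ARG81]

# Push-pull descriptor residues: Loop B' and Loop F' of the middle subunit of
# a consecutive-subunit triplet, measured to Loop E'' of the third subunit.
pushpull:
  loop_b: SER174
  loop_f: LYS189
  loop_e: SER145

# Conserved intersubunit residue pairs monitored for hydrogen bonding
# (principal-side residue first, complementary-side second).
conserved_pairs:
  - [GLU119, ARG147]
  - [LYS49, ASP96]
  - [ASN219, ASN58]
  - [THR220, ARG135]
  - [ASN219, LYS189]

# Loop residue-number ranges (inclusive).  The text names residues inside
# each loop without printing exact termini; these shipped defaults bracket
# the named residues and are overridable.
loops:
  A: [116, 122]
  B: [170, 177]
  C: [215, 224]
  D: [77, 82]
  E: [132, 148]
  F: [185, 195]
  "2": [57, 71]

restrained_tail: [236, 240]

# Molecule classification
water_resnames: [HOH, WAT, TIP3, TIP, SOL, SPC, T3P]
ion_resnames: [NA, CL, SOD, CLA, K, POT, MG, CAL]
ligand_resnames: [GLY, LIG]

# Geometric interaction criteria
criteria:
  hbond_distance_cutoff: 3.0       # donor-acceptor heavy-atom distance, A
  hbond_angle_cutoff: 135.0        # donor-H-acceptor angle, degrees (>=)
  cation_pi_distance_cutoff: 6.0   # cation to ring centre, A
  cation_pi_angle_window: 45.0     # normal/centre->cation angle <45 or >135
  contact_cutoff: 11.0             # Calpha-Calpha contact map threshold, A
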