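# Default cgdroplet force-field parameter file.
#
# Residue-scale implicit-solvent model: one bead per amino acid (20 types)
# plus a three-bead-per-nucleotide ssRNA representation (phosphate PHO,
# ribose RIB, base URA/ADE/GUA/CYT).  All values here are package-calibrated
# defaults on the dimensionless [0, 1] hydrophobicity scale; the RNA bead
# hydrophobicities are produced by the linear Kapcha-Rossky calibration
# below (the kr_values are packaged surrogate calibration inputs chosen so
# the map reproduces the bead table exactly).
#
# Units: energy kJ/mol, length nm, mass amu, charge e.
schema_version: 1

nonbonded:
  # Global depth scale of the Ashbaugh-Hatch hydrophobic term.
  hydrophobic_strength: 1.5
  # Extra attractive well between cationic (R, K) and aromatic (Y, F, W) beads.
  cation_pi_strength: 3.0
  relative_permittivity: 80.0
  # Reference conditions for the Debye screening length.
  ionic_strength_mM: 150.0
  temperature_K: 300.0
  # Single nonbonded cutoff, ~2.5x the Debye length at 150 mM / 300 K
  # (the screened-Coulomb tail there is < 0.1 kJ/mol).
  cutoff_nm: 2.0
  # Pair distances below this are treated as an overlap error.
  min_distance_nm: 1.0e-4

bonded:
  bond_force_constant: 8000.0
  protein_bond_length: 0.38
  rna_bonds:
    phosphate_ribose: 0.37
    ribose_base: 0.43
    ribose_phosphate: 0.37
  angles_enabled: false

hydrophobicity_calibration:
  slope: 0.10657142857142857
  intercept: 0.5418571428571428
  kr_values:
    PHO: -4.0
    RIB: 2.0
    URA: -1.5
    ADE: 0.5
    GUA: -0.5
    CYT: -2.0

beads:
  # --- amino acids (one bead per residue) ---
  A: {mass: 71.08,  charge: 0.0,  epsilon: 0.70, sigma: 0.504, category: aliphatic}
  R: {mass: 156.19, charge: 1.0,  epsilon: 0.35, sigma: 0.656, category: cationic}
  N: {mass: 114.10, charge: 0.0,  epsilon: 0.43, sigma: 0.568, category: hydrophilic}
  D: {mass: 115.09, charge: -1.0, epsilon: 0.28, sigma: 0.558, category: anionic}
  C: {mass: 103.14, charge: 0.0,  epsilon: 0.75, sigma: 0.548, category: hydrophilic}
  Q: {mass: 128.13, charge: 0.0,  epsilon: 0.45, sigma: 0.602, category: hydrophilic}
  E: {mass: 129.12, charge: -1.0, epsilon: 0.28, sigma: 0.592, category: anionic}
  G: {mass: 57.05,  charge: 0.0,  epsilon: 0.57, sigma: 0.450, category: hydrophilic}
  H: {mass: 137.14, charge: 0.0,  epsilon: 0.50, sigma: 0.608, category: hydrophilic}
  I: {mass: 113.16, charge: 0.0,  epsilon: 0.84, sigma: 0.618, category: aliphatic}
  L: {mass: 113.16, charge: 0.0,  epsilon: 0.85, sigma: 0.618, category: aliphatic}
  K: {mass: 128.17, charge: 1.0,  epsilon: 0.30, sigma: 0.636, category: cationic}
  M: {mass: 131.19, charge: 0.0,  epsilon: 0.80, sigma: 0.618, category: aliphatic}
  F: {mass: 147.18, charge: 0.0,  epsilon: 0.90, sigma: 0.636, category: aromatic}
  P: {mass: 97.12,  charge: 0.0,  epsilon: 0.67, sigma: 0.556, category: aliphatic}
  S: {mass: 87.08,  charge: 0.0,  epsilon: 0.47, sigma: 0.518, category: hydrophilic}
  T: {mass: 101.10, charge: 0.0,  epsilon: 0.52, sigma: 0.562, category: hydrophilic}
  W: {mass: 186.21, charge: 0.0,  epsilon: 0.95, sigma: 0.678, category: aromatic}
  Y: {mass: 163.18, charge: 0.0,  epsilon: 0.88, sigma: 0.646, category: aromatic}
  V: {mass: 99.13,  charge: 0.0,  epsilon: 0.76, sigma: 0.586, category: aliphatic}
  # --- RNA beads (3 per nucleotide: phosphate, ribose, base) ---
  PHO: {mass: 94.97,  charge: -1.0, epsilon: 0.11557142857142855, sigma: 0.55, category: backbone-RNA}
  RIB: {mass: 116.12, charge: 0.0,  epsilon: 0.755,               sigma: 0.56, category: backbone-RNA}
  URA: {mass: 111.08, charge: 0.0,  epsilon: 0.382,               sigma: 0.52, category: base-RNA}
  ADE: {mass: 134.12, charge: 0.0,  epsilon: 0.5951428571428571,  sigma: 0.56, category: base-RNA}
  GUA: {mass: 150.12, charge: 0.0,  epsilon: 0.4885714285714286,  sigma: 0.57, category: base-RNA}
  CYT: {mass: 110.09, charge: 0.0,  epsilon: 0.3287142857142857,  sigma: 0.51, category: base-RNA}
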