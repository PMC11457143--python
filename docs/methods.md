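# Methods

## The model

`cgdroplet` simulates liquid-liquid phase separation (LLPS) of intrinsically
disordered proteins and single-stranded RNA with an implicit-solvent,
residue-scale model:

* **Proteins** are linear chains of one bead per amino acid (20 bead types).
* **ssRNA** is three beads per nucleotide — phosphate (PHO), ribose (RIB)
  and base (URA/ADE/GUA/CYT) — bonded P–R and R–B within a nucleotide and
  R–P between consecutive nucleotides, after three-interaction-site RNA
  models.

Each bead type carries a mass, a formal charge, a size parameter sigma and
a dimensionless hydrophobicity `eps_i` on a [0, 1] scale.  The RNA bead
hydrophobicities are produced by a linear calibration from per-bead
Kapcha–Rossky hydrophobicity inputs, `eps_i = slope * KR_i + intercept`,
validated to land in [0, 1].  The calibration inputs packaged here are
surrogate values constructed so that the map reproduces the packaged bead
table exactly (ribose 0.755, uracil 0.382); they are parameter-file data,
not derived from atomistic structures.

### Interactions

All nonbonded terms act between bead pairs at distance `r` (nm) and are
shifted to vanish continuously at a single cutoff `r_c` (2.0 nm by default,
about 2.5 Debye lengths at physiological salt):

1. **Hydrophobic / excluded volume** — an Ashbaugh–Hatch-scaled 12-6 well.
   With `u(r) = 4 e_hp [(s/r)^12 - (s/r)^6]`, `s = (s_i + s_j)/2` and
   `lam = (eps_i + eps_j)/2`:

       U_hp = u(r) + (1 - lam) e_hp     r <= 2^(1/6) s
            = lam u(r)                  otherwise

   so a fully hydrophilic pair sees only the repulsive core.
2. **Cation-pi** — an extra 12-6 well of depth `e_cp` between cationic
   (R, K) and aromatic (Y, F, W) beads.  This sticker class is kept separate
   from generic hydrophobicity because it drives protein–protein
   association (e.g. arginine–tyrosine contacts) that a hydrophobicity
   scale alone cannot represent.
3. **Electrostatics** — Debye–Hückel screened Coulomb,
   `U_el = f q_i q_j exp(-r/lambda_D) / (eps_r r)`, with
   `f = 138.935 kJ mol^-1 nm e^-2`, `eps_r = 80` and `lambda_D` from the
   closed-form expression (0.795 nm at 150 mM, 300 K).  No long-range
   correction is applied; the screened tail at the cutoff is < 0.1 kJ/mol.

Bonds are harmonic (`k = 8000 kJ mol^-1 nm^-2`; 0.38 nm between residues,
0.37/0.43 nm for the RNA backbone/base bonds).  The parameter schema
supports residue-specific angle/torsion terms but the packaged defaults
disable them.

### Calibration of the packaged defaults

Only three hydrophobicities are pinned by external reference: ribose 0.755,
uracil 0.382, proline 0.67.  The remaining bead values, the hydrophobic
depth scale `e_hp = 1.5 kJ/mol` and the cation-pi depth `e_cp = 3.0 kJ/mol`
are package calibration, chosen so the model reproduces the qualitative
phase behavior of the FUS/TDP-43–RNA–DPR family at desk scale:

* pure FUS (PLD+RGG1) forms a stable droplet (aromatic + cation-pi
  cohesion);
* pure U_40 and pure polyPR_60 do **not** phase separate — their
  electrostatic self-repulsion (~1.3 kJ/mol per like-charge contact)
  must exceed the hydrophobic attraction of their stickiest beads, which
  bounds `e_hp` from above (`e_hp * 0.67 < 1.3` for proline–proline);
* U_40 + PR_60 mixtures undergo complex coacervation (arginine–phosphate
  attraction);
* RNA added to a FUS droplet stays outside/at the surface (hydrophilic
  phosphate repelled by the PLD).

Cationic beads get low generic hydrophobicity (R 0.35, K 0.30) because
their sticker behavior is carried by the explicit cation-pi and
electrostatic terms.  An `e_hp` much above ~1.9 kJ/mol makes polyPR
self-attractive and destroys the no-LLPS corners of the ternary diagram;
much below ~1 kJ/mol the FUS droplet evaporates at 300 K.

## Dynamics

* Velocity-Verlet core, 20 fs time step.
* **NVT**: BAOAB Langevin by default, with the friction mapped from the
  thermostat coupling time (`gamma = 1/tau_t`, `tau_t = 100 ps`).  A
  deterministic Nosé–Hoover single-chain thermostat is available behind
  `IntegratorConfig(thermostat="nose-hoover")`; Langevin is the default
  because it equilibrates droplets robustly at these system sizes.
  `thermostat="none"` gives NVE.
* **NPT**: isotropic Berendsen barostat,
  `mu^3 = 1 - kappa dt/tau_p (P0 - P)` with `tau_p = 10 ps`, 1 bar
  reference, `kappa = 4.5e-5 bar^-1`; the instantaneous pressure is the
  pairwise virial estimator `P = (2 KE + sum_ij f_ij . r_ij) / (3V)`.
* **Energy minimization**: short adaptive steepest descent (removes hard
  overlaps) followed by L-BFGS to a max-force tolerance (default
  1 kJ mol^-1 nm^-1); hitting the iteration cap is logged, not fatal.
* Neighbor candidates come from a periodic cell list (KD-tree fallback
  for boxes under three cells per dimension) with a Verlet skin (0.6 nm);
  the list is rebuilt when any displacement exceeds 45% of the skin or
  the box drifts under the barostat.  Pair distances are floored
  at 0.1 nm inside the kernel to keep overlap energies finite; genuine
  overlaps below the parameter file's `min_distance` raise an error.
* All randomness flows from a single seeded PCG64 generator; identical
  (seed, config, inputs) reproduce trajectories bitwise.

Units are GROMACS-style: kJ/mol, nm, ps, amu, e (so 1 amu nm^2 ps^-2 =
1 kJ/mol).

## Droplet protocol

The droplet-formation pipeline mirrors the condensed-start strategy: the
droplet is built first and then challenged with a dilute environment.

1. Chains are generated as random coils (bond lengths honored) with their
   centers of mass on a regular grid in a box at condensed-phase particle
   density (default 2 M in beads, ~25x the final box density, so
   neighboring coils overlap into one droplet).
2. Energy minimization (1 kJ mol^-1 nm^-1).
3. 50 ns NVT at 300 K (full scale).
4. 500 ns NPT at 1 bar (full scale) to relax the droplet density.
5. Chains are unwrapped across periodic images, recentered, and inserted
   into a new cubic box at a total particle density of 80 000 uM
   (V = N / (N_A c), exact).  By default every bead (protein + RNA)
   counts toward N; `density_counts_all_beads=False` restricts the count
   to amino-acid beads.
6. A second minimization, then a 3 us NVT production run sampled every
   5 ns (full scale).

Compositions are percentages of the reference amounts 120 RBP / 267 RNA /
267 DPR molecules (counts rounded to nearest, ties up), which makes the
three pure reference systems bead-count matched at 32 040 beads.

Full scale is cluster-sized.  The `desk` preset divides molecule counts by
24 and runs 0.04 / 0.06 / 0.4 ns stages with a 0.05 ns sampling stride —
problem sizes (~1000–1500 beads) chosen so a full protocol run completes
in about a minute on one CPU.  At this scale the discriminating signal is
directional and follows the protocol's own stability criterion: an
unstable pre-formed droplet breaks up, shedding molecules into a dilute
phase, while a stable one retains them.  With only ~10 chains the
instantaneous largest-cluster fraction of a dispersed system fluctuates
strongly (transient collision clusters), so stability is read from the
time-averaged dilute-phase fraction rather than from cluster size alone.
Quantitative coexistence densities are out of reach at this scale.

## Analyses

* **Contact maps**: an inter-molecular bead pair within 1.0 nm is a
  contact (the cutoff is a reported parameter of every output, since
  residue-scale contact definitions vary).  Maps are averaged over frames
  and normalized by the molecule count of the row species; by-type maps
  are exact sum-aggregations of by-index maps.
* **Interaction fractions** F_int classify by-type contacts as aromatic
  (aromatic–aromatic), cation-pi ({R,K}x{Y,F,W}), electrostatic
  (opposite-charge pairs, phosphate included), aliphatic
  (aliphatic–aliphatic), aromatic–aliphatic, or hydrophilic/other, and
  normalize by the total.
* **Clustering**: single-linkage over molecules, linked when any
  inter-molecular bead pair is within 1.5 nm (minimum image).
* **Phase regions**: LLPS requires the largest cluster to hold >= 50% of
  all beads (frames after a discarded equilibration window, default the
  first third); a species is "in the dilute phase" when >= 10% of its
  molecules sit outside the largest cluster.  Labels: no_LLPS, full_LLPS,
  dilute_RNA, dilute_DPR.
* **Radial profiles** are shell-volume-normalized bead densities about the
  largest cluster's periodic (circular-mean) center of mass; integration
  recovers bead counts to binning error.
* **Charge ratios**: q-/q+ and (q- + N_pi)/q+, with N_pi the protein
  aromatic count (whole system by default; RNA bases excluded unless
  flagged).  The empirical stability band 1–5 is annotated.
* **Morphology**: `separate` when the two largest clusters each hold
  >= 30% of beads with different dominant species; otherwise `core_shell`
  when the gap between innermost and outermost species' mean radii exceeds
  25% of the cluster radius; `marbled` for interleaved multi-species
  clusters; `mixed` for single-species droplets.  All thresholds are
  echoed in the output.

## Synthetic fixtures

`cgdroplet.fixtures` generates seed-deterministic geometric configurations
(ideal gas, uniform sphere, core–shell, two blobs, marbled, lattice pairs)
with ground-truth sidecars (true cluster labels, contact pairs, radii).
They are geometric, not thermodynamic: they validate the analysis and
engine contracts exactly, but passing them says nothing about force-field
realism — that is what the desk-scale protocol checks probe, and those in
turn only test directional behavior, not quantitative phase boundaries of
real systems.

## Known limitations

* The amino-acid hydrophobicity table beyond the three pinned values is a
  package calibration, not a transcription of an external parameter set;
  quantitative observables (densities, surface tensions) should not be
  compared against experiments without re-parametrization.
* Electrostatics are cutoff Debye–Hückel; systems dominated by long-range
  charge ordering need an Ewald-class treatment this package does not
  provide.
* The Berendsen barostat does not sample a true NPT ensemble; it is used
  only for equilibration, matching its role in the protocol.
* Desk-scale droplets hold ~10 chains; finite-size effects are large, and
  the phase labels at this scale are directional indicators only.
* The canonical sequence statistics quoted in the docs ("about half
  glycine" in FUS RGG1, "about two thirds hydrophilic" in the TDP-43 CTD)
  are descriptive roundings; the exact canonical fractions are 54% and
  64.1% and are what the code computes.
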