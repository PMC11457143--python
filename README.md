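# cgdroplet

Coarse-grained, implicit-solvent molecular dynamics and condensate analysis
for protein/RNA liquid-liquid phase separation (LLPS), built around the
biology of C9orf72 ALS/FTD: the RNA-binding proteins FUS (PLD+RGG1,
residues 1-267) and TDP-43 (C-terminal IDR, residues 273-414), dipeptide
repeat proteins (polyPR, polyGR, polyGA, polyGP, polyPA), and
single-stranded poly-U RNA.

Proteins are modeled one bead per amino acid; ssRNA is three beads per
nucleotide (phosphate, ribose, base).  Beads interact through an
Ashbaugh-Hatch hydrophobic term driven by per-bead hydrophobicities
`eps_i` in [0, 1], an explicit cation-pi well between {R, K} and
{Y, F, W}, and Debye-Hueckel screened electrostatics
(`U_el = f q_i q_j exp(-r/lambda_D) / (eps_r r)`).  The whole force field
is a YAML parameter file; the packaged default pins the reference
hydrophobicities (ribose 0.755, uracil 0.382, proline 0.67) and documents
everything else as package calibration.  See `docs/methods.md` for the
model, the droplet protocol, and every analysis convention.

The package answers questions of the form: which ternary
RBP-RNA-DPR compositions phase separate, which morphology does the
condensate adopt (core-shell, marbled, bimodal), which residue contacts
drive it, and how do charge ratios `q-/q+` and `(q- + N_pi)/q+` track
condensate stability?

## Worked example

A desk-scale complex-coacervation run — equal numbers of U_40 and
polyPR_60 chains through the full droplet protocol (grid placement, energy
minimization, NVT, NPT at 1 bar, re-insertion at 80 000 uM, production):

```python
from cgdroplet.protocol import (
    PhaseComposition, ProtocolConfig, compose_system, run_droplet_protocol,
)
from cgdroplet.analysis import charge_ratio, classify_phase

comp = PhaseComposition(0, 50, 50)          # (% RBP, % RNA, % DPR)
species = compose_system(comp, count_scale=1 / 24)
run = run_droplet_protocol(comp, ProtocolConfig.desk(seed=7))

region = classify_phase(run.trajectory, run.topology)
print("phase label:", region.label)
print(f"largest-cluster bead fraction: {region.largest_cluster_fraction:.2f}")
rep = charge_ratio(species)
print(f"q-: {rep.q_minus:.0f}  q+: {rep.q_plus:.0f}  (q-+Npi)/q+: {rep.ratio_pi:.3f}")
```

prints

```
phase label: full_LLPS
largest-cluster bead fraction: 1.00
q-: 240  q+: 360  (q-+Npi)/q+: 0.667
```

The two oppositely charged polyelectrolytes, neither of which phase
separates alone (run the same protocol with `PhaseComposition(0, 100, 0)`
or `(0, 0, 100)` and the pre-formed droplet sheds molecules into a
dilute phase), hold together as a single condensate: every bead stays
in one cluster through the production run.  The charge-ratio report totals
the -40 charge per U_40 strand against the +60 per PR_60 chain; with no
aromatic stickers in either species, `(q- + N_pi)/q+` equals the bare
charge ratio.

The same machinery exposes contact maps (`contact_map`,
`aggregate_by_type`, `interaction_fractions`), cluster detection and
four-region phase classification, radial density profiles about the
condensate center, and morphology labels (`core_shell` / `marbled` /
`mixed` / `separate`).  A thin CLI wraps it:

```sh
cgdroplet sequence --dpr PR:60 --stats
cgdroplet droplet --composition 0,50,50 --preset desk --seed 7 --out run1
cgdroplet analyze phase run1
```

## Layout

- `src/cgdroplet/sequences.py` — species construction, packaged canonical
  FUS/TDP-43 fragments, FASTA I/O, composition statistics
- `src/cgdroplet/forcefield.py` — bead table, hydrophobicity calibration,
  energies/forces, topologies (parameter-file driven)
- `src/cgdroplet/engine.py` — minimization, Langevin/Nose-Hoover NVT,
  Berendsen NPT, neighbor lists, trajectories
- `src/cgdroplet/protocol.py` — droplet pipeline and ternary composition
  bookkeeping (reference amounts 120 RBP / 267 RNA / 267 DPR)
- `src/cgdroplet/analysis.py` — condensate observables
- `src/cgdroplet/fixtures.py` — synthetic ground-truth configurations
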