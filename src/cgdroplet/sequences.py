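"""Molecular species: RNA-binding protein fragments, dipeptide repeats, poly-U RNA.

Proteins are represented one bead per amino acid; single-stranded RNA is
represented three beads per nucleotide (phosphate, ribose, base, in 5'->3'
order).  The module builds and annotates every species used in the droplet
simulations: the packaged canonical RBP fragments (FUS PLD+RGG1, residues
1-267; TDP-43 C-terminal IDR, residues 273-414), the five dipeptide repeat
proteins (PR, GR, GA, GP, PA) at arbitrary repeat number, and homopolymeric
RNA such as U_40.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
RNA_BASES = "ACGU"

#: codes of the five dipeptide repeat units translated from the C9orf72
#: G4C2 repeat expansion
DPR_UNITS = ("PR", "GR", "GA", "GP", "PA")

#: one-letter base code -> three-letter base bead code
BASE_BEAD = {"U": "URA", "A": "ADE", "G": "GUA", "C": "CYT"}

#: simple formal-charge convention used for bookkeeping reports
FORMAL_CHARGE = {"R": 1, "K": 1, "D": -1, "E": -1}

AROMATIC_RESIDUES = frozenset("YFW")


class UnknownSpeciesError(KeyError):
    """Requested a sequence fixture or unit code that is not packaged."""


@dataclass
class ProteinSequence:
    """A linear protein chain with optional named domains.

    ``domains`` maps a domain name to a 1-based inclusive residue range in
    *reported* numbering; ``first_residue`` shifts the reported numbering so
    fragments excised from a larger protein (e.g. TDP-43 273-414) keep their
    original residue numbers.
    """

    name: str
    residues: str
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    first_residue: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.name}: non-canonical residue code(s) {sorted(bad)}"
            )
        last = self.first_residue + len(self.residues) - 1
        for dom, (a, b) in self.domains.items():
            if not (self.first_residue <= a <= b <= last):
                raise ValueError(
                    f"{self.name}: domain {dom}={a}-{b} outside "
                    f"{self.first_residue}-{last}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bead_codes(self) -> list[str]:
        """Bead type code per bead (identity for 1-bead-per-residue chains)."""
        return list(self.residues)

    def domain_slice(self, domain: str) -> str:
        a, b = self.domains[domain]
        off = self.first_residue
        return self.residues[a - off : b - off + 1]

    def net_formal_charge(self) -> int:
        return sum(FORMAL_CHARGE.get(c, 0) for c in self.residues)


@dataclass
class RNASequence:
    """A single-stranded RNA chain, expanded to 3 beads per nucleotide.

    Each nucleotide contributes exactly one phosphate, one ribose and one
    base bead, in 5'->3' order.  The phosphate bead carries the chain's
    formal charge (one negative charge per nucleotide by the packaged
    convention, including the 5' terminus; the value itself lives in the
    force-field parameter file and can be overridden there).
    """

    name: str
    nucleotides: str
    beads_per_nucleotide: int = 3

    def __post_init__(self) -> None:
        bad = set(self.nucleotides) - set(RNA_BASES)
        if bad:
            raise ValueError(f"{self.name}: unknown base code(s) {sorted(bad)}")
        if self.beads_per_nucleotide != 3:
            raise ValueError("the ssRNA model is fixed at 3 beads per nucleotide")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_beads(self) -> int:
        return 3 * len(self.nucleotides)

    @property
    def bead_codes(self) -> list[str]:
        codes: list[str] = []
        for base in self.nucleotides:
            codes.extend(("PHO", "RIB", BASE_BEAD[base]))
        return codes

    def net_formal_charge(self) -> int:
        return -len(self.nucleotides)


@dataclass(frozen=True)
class DPRSpec:
    """A dipeptide repeat protein: one of the five C9orf72 DPR units."""

    unit: str
    n_repeats: int

    def __post_init__(self) -> None:
        if self.unit not in DPR_UNITS:
            raise UnknownSpeciesError(
                f"unknown DPR unit {self.unit!r}; allowed units: "
                + ", ".join(DPR_UNITS)
            )
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


Molecule = Union[ProteinSequence, RNASequence]


def build_dpr_sequence(spec: DPRSpec) -> ProteinSequence:
    """Expand a dipeptide repeat spec into an alternating protein sequence.

    ``DPRSpec("PR", 60)`` yields the 120-residue polyPR_60 chain containing
    60 arginines.  The name encodes unit and repeat count (``PR_60``).
    """
    if not isinstance(spec, DPRSpec):
        spec = DPRSpec(*spec)
    seq = spec.unit * spec.n_repeats
    return ProteinSequence(name=f"{spec.unit}_{spec.n_repeats}", residues=seq)


def build_rna_sequence(n_nucleotides: int, base: str = "U") -> RNASequence:
    """Build a homopolymeric ssRNA strand (default poly-U), e.g. U_40."""
    if n_nucleotides < 1:
        raise ValueError("n_nucleotides must be >= 1")
    if base not in RNA_BASES:
        raise ValueError(f"unknown base {base!r}; allowed: {RNA_BASES}")
    return RNASequence(name=f"{base}_{n_nucleotides}", nucleotides=base * n_nucleotides)


# ---------------------------------------------------------------------------
# packaged canonical fixtures
# ---------------------------------------------------------------------------

_RBP_DOMAINS = {
    "FUS_PLD_RGG1": {"first": 1, "domains": {"PLD": (1, 167), "RGG1": (168, 267)}},
    "TDP43_CTD": {"first": 273, "domains": {"CTD": (273, 414)}},
}


def _packaged_fasta() -> Path:
    return Path(resources.files("cgdroplet") / "data" / "rbp_sequences.fasta")


def available_rbp_fixtures() -> list[str]:
    return sorted(_RBP_DOMAINS)


def get_rbp_sequence(name: str) -> ProteinSequence:
    """Load a packaged canonical RBP fragment by name.

    ``FUS_PLD_RGG1`` is human FUS residues 1-267 (PLD 1-167, RGG1 168-267);
    ``TDP43_CTD`` is the human TDP-43 C-terminal IDR, residues 273-414 in
    original full-protein numbering.
    """
    if name not in _RBP_DOMAINS:
        raise UnknownSpeciesError(
            f"unknown RBP fixture {name!r}; available: "
            + ", ".join(available_rbp_fixtures())
        )
    records = read_fasta(_packaged_fasta())
    for rec_name, seq in records:
        if rec_name == name:
            meta = _RBP_DOMAINS[name]
            return ProteinSequence(
                name=name,
                residues=seq,
                domains=dict(meta["domains"]),
                first_residue=meta["first"],
            )
    raise UnknownSpeciesError(f"fixture {name!r} missing from packaged FASTA")


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------

@dataclass
class SequenceStatistics:
    """Composition report used by the charge-ratio and sticker analyses.

    ``n_pi`` counts protein aromatic residues (Y, F, W) only; RNA bases are
    excluded by default since the charge-ratio metric is defined over protein
    stickers.  Pass ``count_rna_aromatics=True`` to ``sequence_statistics``
    to override.
    """

    counts: dict[str, int]
    q_plus: float
    q_minus: float
    n_pi: int
    n_aromatic: int
    n_aliphatic: int
    n_hydrophilic: int

    def __add__(self, other: "SequenceStatistics") -> "SequenceStatistics":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return SequenceStatistics(
            counts=dict(merged),
            q_plus=self.q_plus + other.q_plus,
            q_minus=self.q_minus + other.q_minus,
            n_pi=self.n_pi + other.n_pi,
            n_aromatic=self.n_aromatic + other.n_aromatic,
            n_aliphatic=self.n_aliphatic + other.n_aliphatic,
            n_hydrophilic=self.n_hydrophilic + other.n_hydrophilic,
        )


def sequence_statistics(
    seq: Molecule | str,
    *,
    params=None,
    count_rna_aromatics: bool = False,
) -> SequenceStatistics:
    """Per-type counts and charge/sticker totals for one molecule.

    Charges and sticker categories are taken from the force-field bead table
    (``params``; the packaged default is used when omitted), so the report
    stays consistent with whatever parameter file drives the simulation.
    """
    if isinstance(seq, str):
        seq = ProteinSequence(name="anonymous", residues=seq)
    codes = seq.bead_codes if not isinstance(seq, str) else list(seq)

    if params is None:
        from cgdroplet.forcefield import default_forcefield

        params = default_forcefield()
    table = params.bead_types

    counts: Counter[str] = Counter(codes)
    q_plus = q_minus = 0.0
    n_pi = n_arom = n_aliph = n_hyd = 0
    for code, n in counts.items():
        bt = table[code]
        if bt.charge > 0:
            q_plus += n * bt.charge
        elif bt.charge < 0:
            q_minus += n * (-bt.charge)
        if bt.category == "aromatic":
            n_arom += n
            n_pi += n
        elif bt.category == "aliphatic":
            n_aliph += n
        elif bt.category == "hydrophilic":
            n_hyd += n
        elif bt.category == "base-RNA" and count_rna_aromatics:
            n_pi += n
    return SequenceStatistics(
        counts=dict(counts),
        q_plus=q_plus,
        q_minus=q_minus,
        n_pi=n_pi,
        n_aromatic=n_arom,
        n_aliphatic=n_aliph,
        n_hydrophilic=n_hyd,
    )


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(name, sequence)`` pairs."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq)))
    return out


def write_fasta(path, sequences: Iterable[Molecule]) -> None:
    """Write protein or RNA sequences to FASTA (proteins as residues,
    RNA as nucleotides)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for s in sequences:
        letters = s.residues if isinstance(s, ProteinSequence) else s.nucleotides
        records.append(SeqRecord(Seq(letters), id=s.name, description=""))
    seqio_write(records, str(path), "fasta")
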