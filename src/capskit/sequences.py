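"""Nucleotide sequences, IUPAC degeneracy tables and FASTA round-trips.

Sequences are plain upper-case ACGT strings wrapped in a small immutable
record.  Degenerate IUPAC codes are legal in enzyme recognition motifs but
not, by default, in template sequences: the templates this toolkit targets
are Sanger-resolved amplicons, so an ambiguity code in the input is almost
always a base-calling problem rather than information.  Opt-in handling of
ambiguous template bases lives in :mod:`capskit.enzymes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Expansion set of every IUPAC nucleotide code.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class SequenceError(ValueError):
    """Invalid nucleotide sequence or alphabet violation."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_bases(bases: str, *, allow_iupac: bool = False) -> None:
    """Raise :class:`SequenceError` naming the first offending position."""
    alphabet = IUPAC_CODES.keys() if allow_iupac else "ACGT"
    for i, b in enumerate(bases):
        if b not in alphabet:
            raise SequenceError(
                f"invalid base {b!r} at position {i} (alphabet {'IUPAC' if allow_iupac else 'ACGT'})"
            )


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-case ACGT sequence with an identifier.

    Lower-case input is accepted and canonicalised; anything outside ACGT
    (including IUPAC ambiguity codes) is rejected with the offending
    position named.  Empty sequences are rejected.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if not self.bases:
            raise SequenceError(f"sequence {self.id!r} is empty")
        validate_bases(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, item):
        return self.bases[item]

    @property
    def length(self) -> int:
        return len(self.bases)

    def reverse_complement(self, id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(id or f"{self.id}_rc", reverse_complement(self.bases))

    def with_bases(self, bases: str, id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(id or self.id, bases)


def read_fasta(path: str | Path, record_id: str | None = None) -> NucleotideSequence:
    """Read one record from a FASTA file.

    The first record is returned unless ``record_id`` selects another.
    """
    records = {r.id: r for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if record_id is None:
        rec = next(iter(records.values()))
    else:
        try:
            rec = records[record_id]
        except KeyError:
            raise SequenceError(f"record {record_id!r} not found in {path}") from None
    return NucleotideSequence(rec.id, str(rec.seq))


def read_fasta_all(path: str | Path) -> Iterator[NucleotideSequence]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield NucleotideSequence(rec.id, str(rec.seq))


def write_fasta(path: str | Path, seqs: NucleotideSequence | list[NucleotideSequence]) -> None:
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
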