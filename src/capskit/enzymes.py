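"""Restriction enzymes with degenerate motifs: site scanning and digestion.

The engine models type II enzymes by their IUPAC recognition motif plus two
cut offsets, one per strand, both measured in phosphodiester-bond
coordinates from the 5' end of the top-strand motif match.  Offsets may lie
outside the motif (type IIS "outside cutters" such as BsmAI).  Fragment
sizes are computed from top-strand cuts only, which is how restriction
patterns are read on a gel: a few nucleotides of 5'/3' overhang do not
shift a band.

Coordinates are 0-based half-open throughout; a cut position ``k`` means
the bond between base ``k-1`` and base ``k`` is severed.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .sequences import (
    IUPAC_CODES,
    NucleotideSequence,
    SequenceError,
    reverse_complement,
    validate_bases,
)


class EnzymeError(ValueError):
    """Malformed enzyme definition or recognition notation."""


def iupac_match(motif_char: str, base: str, mode: str = "reject") -> bool:
    """True iff ``base`` lies in the expansion set of IUPAC code ``motif_char``.

    ``base`` is normally a concrete A/C/G/T.  When the scanned sequence
    itself carries ambiguity codes the ``mode`` decides: ``"optimistic"``
    counts any overlap of the two expansion sets as a match,
    ``"pessimistic"`` requires the base's expansion to be contained in the
    motif code's, and the default ``"reject"`` refuses ambiguous bases.
    """
    try:
        motif_set = IUPAC_CODES[motif_char.upper()]
    except KeyError:
        raise EnzymeError(f"invalid IUPAC code {motif_char!r} in motif") from None
    b = base.upper()
    if b in "ACGT":
        return b in motif_set
    try:
        base_set = IUPAC_CODES[b]
    except KeyError:
        raise SequenceError(f"invalid base {base!r}") from None
    if mode == "reject":
        raise SequenceError(f"ambiguous base {base!r} in sequence (mode='reject')")
    if mode == "optimistic":
        return bool(motif_set & base_set)
    if mode == "pessimistic":
        return base_set <= motif_set
    raise ValueError(f"unknown ambiguity mode {mode!r}")


_REBASE_IIS = re.compile(r"^([ACGTRYSWKMBDHVN]+)\((-?\d+)/(-?\d+)\)$")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: name, IUPAC motif, strand-specific cut offsets.

    ``cut_offset_top`` / ``cut_offset_bottom`` are bond positions counted
    from the 5' end of the top-strand motif match; either may be negative
    or exceed the motif length for outside cutters.
    """

    name: str
    motif: str
    cut_offset_top: int
    cut_offset_bottom: int
    comment: str = ""

    def __post_init__(self) -> None:
        if not self.motif:
            raise EnzymeError(f"{self.name}: empty motif")
        for ch in self.motif:
            if ch.upper() not in IUPAC_CODES:
                raise EnzymeError(f"{self.name}: invalid IUPAC code {ch!r} in motif")
        object.__setattr__(self, "motif", self.motif.upper())

    @property
    def is_palindromic(self) -> bool:
        """Motif equals its own IUPAC reverse complement."""
        return self.motif == reverse_complement(self.motif)

    @classmethod
    def from_rebase(cls, name: str, notation: str, comment: str = "") -> "RestrictionEnzyme":
        """Parse REBASE-style cut notation.

        Two dialects are supported:

        * caret inside the motif, e.g. ``GCN^NGC`` or ``G^GTNACC`` — the
          bottom-strand cut is mirrored through the (palindromic) motif;
        * trailing ``(t/b)`` for outside cutters, e.g. ``GTCTC(1/5)`` —
          offsets count bonds past the 3' end of the motif.
        """
        notation = notation.strip().upper()
        m = _REBASE_IIS.match(notation)
        if m:
            motif, t, b = m.group(1), int(m.group(2)), int(m.group(3))
            return cls(name, motif, len(motif) + t, len(motif) + b, comment)
        if "^" in notation:
            motif = notation.replace("^", "")
            top = notation.index("^")
            enz = cls(name, motif, top, len(motif) - top, comment)
            if not enz.is_palindromic:
                raise EnzymeError(
                    f"{name}: caret notation requires a palindromic motif, got {motif}"
                )
            return enz
        raise EnzymeError(f"{name}: unrecognized cut notation {notation!r}")

    def to_rebase(self) -> str:
        n = len(self.motif)
        if self.cut_offset_top > n or self.cut_offset_top < 0:
            return f"{self.motif}({self.cut_offset_top - n}/{self.cut_offset_bottom - n})"
        return f"{self.motif[: self.cut_offset_top]}^{self.motif[self.cut_offset_top:]}"


@dataclass(frozen=True)
class RecognitionSite:
    """One motif match located on a linear top-strand coordinate system.

    ``start`` is the 0-based start of the motif footprint on the top
    strand regardless of ``strand``; ``cut_position_top`` is the resulting
    top-strand cut.  ``cut_in_sequence`` is False when the cut would fall
    at or beyond either end of the template (such sites never contribute a
    fragment boundary).
    """

    start: int
    strand: str
    cut_position_top: int
    cut_in_sequence: bool


@dataclass(frozen=True)
class FragmentPattern:
    """Multiset of digestion fragment lengths, reported sorted descending."""

    fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fragments", tuple(sorted(self.fragments, reverse=True))
        )

    @property
    def total(self) -> int:
        return sum(self.fragments)

    def resolvable(self, min_visible_bp: int) -> tuple[bool, ...]:
        """Per-fragment visibility flags under a gel-resolution threshold."""
        return tuple(f >= min_visible_bp for f in self.fragments)

    def visible(self, min_visible_bp: int) -> tuple[int, ...]:
        return tuple(f for f in self.fragments if f >= min_visible_bp)

    def as_multiset(self) -> Counter:
        return Counter(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __str__(self) -> str:
        return "-".join(str(f) for f in self.fragments) + " bp"


def _regex_for(motif: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + "".join(sorted(IUPAC_CODES[c])) + "]"
        for c in motif
    )
    return re.compile(f"(?=({body}))")


def _naive_offsets(bases: str, motif: str, mode: str) -> list[int]:
    hits = []
    n, m = len(bases), len(motif)
    for s in range(n - m + 1):
        if all(iupac_match(motif[j], bases[s + j], mode) for j in range(m)):
            hits.append(s)
    return hits


def scan_sites(
    seq: NucleotideSequence | str,
    enzyme: RestrictionEnzyme,
    ambiguity: str = "reject",
) -> list[RecognitionSite]:
    """All recognition sites of ``enzyme`` on a linear template, both strands.

    Bottom-strand sites are located by matching the motif's reverse
    complement on the top strand; their top-strand cut mirrors the
    enzyme's bottom-strand offset.  For palindromic motifs the + and −
    match at each locus is the same physical site and is deduplicated.
    """
    if isinstance(seq, NucleotideSequence):
        bases = seq.bases
    else:
        bases = seq.upper()
        validate_bases(bases, allow_iupac=(ambiguity != "reject"))
        if ambiguity == "reject":
            validate_bases(bases)
    n = len(bases)
    motif = enzyme.motif
    m = len(motif)
    pure = all(b in "ACGT" for b in bases)

    if pure:
        fwd_hits = [mm.start() for mm in _regex_for(motif).finditer(bases)]
    else:
        fwd_hits = _naive_offsets(bases, motif, ambiguity)

    def cleaves(cut_top: int, cut_bottom: int) -> bool:
        # double-strand cleavage needs both cuts on the template; a cut at
        # the very end would only nick or leave a zero-length fragment
        return 0 < cut_top < n and 0 <= cut_bottom <= n

    sites: list[RecognitionSite] = []
    for s in fwd_hits:
        cut = s + enzyme.cut_offset_top
        sites.append(RecognitionSite(s, "+", cut, cleaves(cut, s + enzyme.cut_offset_bottom)))

    if enzyme.is_palindromic:
        return sites

    rc = reverse_complement(motif)
    if pure:
        rev_hits = [mm.start() for mm in _regex_for(rc).finditer(bases)]
    else:
        rev_hits = _naive_offsets(bases, rc, ambiguity)
    for s in rev_hits:
        # enzyme bound to the bottom strand: its bottom-strand offset lands
        # on the sequence's top strand, mirrored through the footprint
        cut = s + m - enzyme.cut_offset_bottom
        sites.append(RecognitionSite(s, "-", cut, cleaves(cut, s + m - enzyme.cut_offset_top)))
    sites.sort(key=lambda r: (r.start, r.strand))
    return sites


def cut_positions(
    seq: NucleotideSequence | str,
    enzyme: RestrictionEnzyme,
    ambiguity: str = "reject",
) -> list[int]:
    """Sorted, deduplicated in-sequence top-strand cut positions."""
    return sorted(
        {s.cut_position_top for s in scan_sites(seq, enzyme, ambiguity) if s.cut_in_sequence}
    )


def digest(
    seq: NucleotideSequence | str,
    enzyme: RestrictionEnzyme,
    ambiguity: str = "reject",
) -> FragmentPattern:
    """Fragment pattern of a complete digest of a linear template.

    Fragments are the intervals between sorted in-sequence cuts plus the
    two template ends; duplicate cut positions are merged so zero-length
    fragments never arise.  No cut site gives one full-length fragment.
    """
    return digest_multi(seq, [enzyme], ambiguity)


def digest_multi(
    seq: NucleotideSequence | str,
    enzymes: list[RestrictionEnzyme],
    ambiguity: str = "reject",
) -> FragmentPattern:
    """Complete double (or n-fold) digest: union of all enzymes' cuts."""
    n = len(seq.bases if isinstance(seq, NucleotideSequence) else seq)
    cuts: set[int] = set()
    for enz in enzymes:
        cuts.update(cut_positions(seq, enz, ambiguity))
    bounds = [0, *sorted(cuts), n]
    return FragmentPattern(tuple(b - a for a, b in zip(bounds, bounds[1:])))


# ---------------------------------------------------------------------------
# enzyme table I/O

_BUNDLED = "enzymes.tsv"


def parse_enzyme_table(text: str) -> list[RestrictionEnzyme]:
    enzymes = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 2:
            raise EnzymeError(f"enzyme table line {lineno}: expected name<TAB>recognition")
        name, recognition = parts[0], parts[1]
        comment = parts[2] if len(parts) > 2 else ""
        enzymes.append(RestrictionEnzyme.from_rebase(name, recognition, comment))
    return enzymes


def load_enzyme_table(path: str | Path | None = None) -> list[RestrictionEnzyme]:
    """Load a TSV enzyme table; with no path, the bundled five-enzyme table."""
    if path is None:
        text = resources.files("capskit").joinpath("data").joinpath(_BUNDLED).read_text()
    else:
        text = Path(path).read_text()
    return parse_enzyme_table(text)


def dump_enzyme_table(enzymes: list[RestrictionEnzyme]) -> str:
    lines = ["name\trecognition\tcomment"]
    for e in enzymes:
        lines.append(f"{e.name}\t{e.to_rebase()}\t{e.comment}")
    return "\n".join(lines) + "\n"


def enzyme_by_name(name: str, enzymes: list[RestrictionEnzyme] | None = None) -> RestrictionEnzyme:
    for e in enzymes if enzymes is not None else load_enzyme_table():
        if e.name.lower() == name.lower():
            return e
    raise EnzymeError(f"enzyme {name!r} not in table")
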