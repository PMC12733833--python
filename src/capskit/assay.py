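"""CAPS and dCAPS assay design and evaluation.

A CAPS (cleaved amplified polymorphic sequence) assay genotypes a SNP by
finding a restriction enzyme whose recognition site is created or
destroyed by the polymorphism, so that the wild-type and resistant PCR
products digest into different band patterns.  When no natural site
overlaps the SNP, a dCAPS assay engineers one: a primer carrying a small
number of deliberate mismatches rewrites bases next to the SNP so that,
together with one allele's base, a recognition site is completed in the
PCR product of that allele only.

Genotype scoring follows gel logic: a heterozygote carries both allele
products, so its band set is the union of the two homozygote band sets;
an assay discriminates when the resolvable band sets of the two
homozygotes differ (for every known resistant allele at multi-allelic
sites — a single enzyme must separate them all, or the design is
rejected and sequencing remains the fallback).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .enzymes import FragmentPattern, RestrictionEnzyme, digest
from .sequences import IUPAC_CODES, NucleotideSequence, reverse_complement


class AssayError(ValueError):
    """Invalid assay geometry, primer placement or variant definition."""


@dataclass(frozen=True)
class VariantSpec:
    """A substitution variant inside an amplicon.

    ``position`` is the 0-based offset of the first variable nucleotide in
    the amplicon product; ``wt`` and each entry of ``res`` are equal-length
    nucleotide strings (single base for a SNP, a codon for multi-nucleotide
    variants).  Multi-allelic resistant sites list one entry per known
    resistant variant.
    """

    label: str
    position: int
    wt: str
    res: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt", self.wt.upper())
        object.__setattr__(self, "res", tuple(r.upper() for r in self.res))
        if not self.res:
            raise AssayError(f"{self.label}: at least one resistant allele required")
        for r in self.res:
            if len(r) != len(self.wt):
                raise AssayError(
                    f"{self.label}: allele {r} length differs from wt {self.wt} "
                    "(substitutions only, no indels)"
                )
            if r == self.wt:
                raise AssayError(f"{self.label}: resistant allele equals wt")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.wt, *self.res)


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product on a template.

    The product spans from the forward primer's 5' end through the reverse
    primer's 5' end inclusive, with primer-encoded bases substituted into
    the product (a mismatch primer overwrites the template base, as in
    real PCR).  Reverse primers are given 5'->3' on the bottom strand.
    """

    template_id: str
    fwd_primer: str
    rev_primer: str
    product: NucleotideSequence
    start: int  # offset of the product on the template top strand
    mismatch_positions: tuple[int, ...] = ()  # product coords rewritten by primers

    @property
    def expected_length(self) -> int:
        return len(self.product)


def _approx_find(template: str, query: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, n_mismatch) of every placement with <= max_mismatch mismatches."""
    hits = []
    n, m = len(template), len(query)
    for s in range(n - m + 1):
        mm = 0
        for a, b in zip(template[s : s + m], query):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append((s, mm))
    return hits


def extract_amplicon(
    template: NucleotideSequence,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    product_id: str | None = None,
) -> Amplicon:
    """In-silico PCR: locate the primer pair and return the product.

    Errors distinguish the three failure modes: a primer that does not
    bind, a primer with multiple binding sites, and primers bound in
    inconsistent orientation (reverse site not downstream of forward).
    """
    fwd = fwd.upper()
    rev = rev.upper()
    if min(len(fwd), len(rev)) < 15:
        raise AssayError("primers must be >= 15 nt")
    rev_rc = reverse_complement(rev)

    fwd_hits = _approx_find(template.bases, fwd, max_mismatch)
    rev_hits = _approx_find(template.bases, rev_rc, max_mismatch)
    for name, seq5p, hits in (("forward", fwd, fwd_hits), ("reverse", rev, rev_hits)):
        if not hits:
            hint = ""
            other = _approx_find(template.bases, reverse_complement(seq5p), max_mismatch)
            if other:
                hint = " (it matches the opposite strand: check primer orientation)"
            raise AssayError(
                f"{name} primer not found on template {template.id!r} "
                f"with <= {max_mismatch} mismatches{hint}"
            )
        if len(hits) > 1:
            raise AssayError(
                f"{name} primer binds template {template.id!r} at "
                f"{len(hits)} positions {[h[0] for h in hits]}: not specific"
            )
    f_start = fwd_hits[0][0]
    r_start = rev_hits[0][0]
    r_end = r_start + len(rev)
    if r_start < f_start + len(fwd):
        raise AssayError(
            "primers oriented inconsistently: reverse primer site "
            f"(start {r_start}) is not downstream of the forward primer (start {f_start})"
        )
    bases = list(template.bases[f_start:r_end])
    mismatches = []
    for i, b in enumerate(fwd):
        if bases[i] != b:
            mismatches.append(i)
            bases[i] = b
    off = len(bases) - len(rev)
    for i, b in enumerate(rev_rc):
        if bases[off + i] != b:
            mismatches.append(off + i)
            bases[off + i] = b
    product = NucleotideSequence(product_id or f"{template.id}_amplicon", "".join(bases))
    return Amplicon(template.id, fwd, rev, product, f_start, tuple(sorted(mismatches)))


def apply_variant(
    seq: Amplicon | NucleotideSequence,
    variant: VariantSpec,
    allele: str,
) -> NucleotideSequence:
    """Substitute one allele of ``variant`` into an amplicon product.

    ``allele`` is ``"wt"``, ``"res"`` (single resistant allele only) or the
    allele string itself.
    """
    product = seq.product if isinstance(seq, Amplicon) else seq
    if allele == "wt":
        bases = variant.wt
    elif allele == "res":
        if len(variant.res) > 1:
            raise AssayError(
                f"{variant.label}: 'res' is ambiguous ({len(variant.res)} resistant alleles)"
            )
        bases = variant.res[0]
    else:
        bases = allele.upper()
        if bases not in variant.alleles:
            raise AssayError(f"{variant.label}: unknown allele {allele!r}")
    pos = variant.position
    if not (0 <= pos and pos + len(bases) <= len(product)):
        raise AssayError(
            f"{variant.label}: position {pos} (+{len(bases)} nt) outside product "
            f"of length {len(product)}"
        )
    new = product.bases[:pos] + bases + product.bases[pos + len(bases) :]
    return product.with_bases(new, f"{product.id}|{variant.label}={bases}")


# ---------------------------------------------------------------------------
# assay evaluation


def _band_sets_differ(
    a: tuple[int, ...], b: tuple[int, ...], min_separation_frac: float
) -> list[int]:
    """Bands present in one set but with no co-migrating partner in the other.

    Two bands co-migrate when their lengths differ by less than
    ``min_separation_frac`` of the larger.  Returns the distinguishing band
    lengths (empty list: the lanes look identical on a gel).
    """

    def unmatched(xs, ys):
        out = []
        for x in xs:
            if not any(x == y or abs(x - y) < min_separation_frac * max(x, y) for y in ys):
                out.append(x)
        return out

    return unmatched(a, b) + unmatched(b, a)


@dataclass(frozen=True)
class AssayDesign:
    """A candidate CAPS assay: one enzyme against one variant on one amplicon."""

    variant: VariantSpec
    enzyme: RestrictionEnzyme
    allele_patterns: dict[str, FragmentPattern]
    genotype_patterns: dict[str, tuple[int, ...]]  # resolvable band sets, first res allele
    per_res_patterns: dict[str, dict[str, tuple[int, ...]]]
    discriminates: bool
    score: tuple
    min_visible_bp: int
    min_separation_frac: float

    def bands(self, genotype: str, res_allele: str | None = None) -> tuple[int, ...]:
        res = res_allele or self.variant.res[0]
        return self.per_res_patterns[res][genotype]


def evaluate_assay(
    amplicon: Amplicon | NucleotideSequence,
    variant: VariantSpec,
    enzyme: RestrictionEnzyme,
    min_visible_bp: int = 20,
    min_separation_frac: float = 0.05,
) -> AssayDesign:
    """Digest every allele's product and decide whether the enzyme genotypes.

    Per-genotype band sets use gel logic (het = union of homozygote bands);
    fragments below ``min_visible_bp`` are flagged unresolvable and ignored
    for discrimination, and bands closer than ``min_separation_frac`` of
    the larger are treated as co-migrating.
    """
    allele_patterns: dict[str, FragmentPattern] = {}
    for allele in variant.alleles:
        seq = apply_variant(amplicon, variant, allele)
        allele_patterns[allele] = digest(seq, enzyme)

    wt_vis = allele_patterns[variant.wt].visible(min_visible_bp)
    per_res: dict[str, dict[str, tuple[int, ...]]] = {}
    diffs_per_res = []
    for r in variant.res:
        r_vis = allele_patterns[r].visible(min_visible_bp)
        het = tuple(sorted(set(wt_vis) | set(r_vis), reverse=True))
        per_res[r] = {"SS": wt_vis, "RR": r_vis, "RS": het}
        diffs_per_res.append(_band_sets_differ(wt_vis, r_vis, min_separation_frac))
    discriminates = all(len(d) > 0 for d in diffs_per_res)
    n_disc = min(len(d) for d in diffs_per_res)
    smallest_informative = min((min(d) for d in diffs_per_res if d), default=0)
    total_bands = sum(len(p.fragments) for p in allele_patterns.values())
    score = (n_disc, smallest_informative, -total_bands)
    return AssayDesign(
        variant=variant,
        enzyme=enzyme,
        allele_patterns=allele_patterns,
        genotype_patterns=per_res[variant.res[0]],
        per_res_patterns=per_res,
        discriminates=discriminates,
        score=score,
        min_visible_bp=min_visible_bp,
        min_separation_frac=min_separation_frac,
    )


def design_caps(
    amplicon: Amplicon | NucleotideSequence,
    variant: VariantSpec,
    enzyme_library: list[RestrictionEnzyme],
    min_visible_bp: int = 20,
    min_separation_frac: float = 0.05,
) -> list[AssayDesign]:
    """Rank every library enzyme that differentially digests the two alleles.

    An empty result is a meaningful outcome: no plain CAPS assay exists
    and a dCAPS design (or sequencing) is the fallback.
    """
    if not enzyme_library:
        raise AssayError("enzyme library is empty")
    designs = [
        evaluate_assay(amplicon, variant, enz, min_visible_bp, min_separation_frac)
        for enz in enzyme_library
    ]
    hits = [d for d in designs if d.discriminates]
    hits.sort(key=lambda d: d.score, reverse=True)
    return hits


# ---------------------------------------------------------------------------
# dCAPS primer engineering


@dataclass(frozen=True)
class DcapsPrimer:
    """A mismatch primer that engineers an allele-specific restriction site.

    ``modified`` shows introduced mismatches in lower case (display
    convention for engineered bases).  ``orientation`` is "rev" for a
    bottom-strand primer (the usual dCAPS layout) or "fwd".
    """

    original: str
    modified: str
    mismatch_positions: tuple[int, ...]  # indices within the primer, 5'->3'
    orientation: str
    binding_start: int  # top-strand start of the primer footprint
    engineered_enzyme: RestrictionEnzyme
    cutting_allele: str  # allele whose product acquires the engineered site
    allele_patterns: dict[str, FragmentPattern]

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def _first_concrete(code: str) -> str:
    return min(IUPAC_CODES[code])


def design_dcaps(
    template: NucleotideSequence,
    variant: VariantSpec,
    enzyme: RestrictionEnzyme,
    primer_anchor_window: int = 10,
    k_max: int = 2,
    protected_3prime: int = 3,
    primer_length: int = 26,
) -> list[DcapsPrimer]:
    """Enumerate mismatch primers that create an allele-specific site.

    The engineered recognition site must span the variant base, so the
    primer is anchored with its 3' end within ``primer_anchor_window``
    nucleotides of the variant (downstream for a reverse primer, upstream
    for a forward primer) without covering the variant itself — the
    diagnostic base must come from the genomic allele, never from the
    primer.  At most ``k_max`` mismatches are introduced, none within the
    ``protected_3prime`` terminal window (a 3'-terminal mismatch would
    abort extension).  Candidates are verified by digesting both allele
    products; only differentially cutting primers are returned, sorted by
    mismatch count.  ``k_max=0`` degenerates to plain CAPS through primer
    placement.

    Template coordinates define the product: for a reverse primer the
    product runs from template position 0 through the primer footprint;
    for a forward primer, from the footprint to the template end.
    """
    if len(variant.wt) != 1 or any(len(r) != 1 for r in variant.res):
        raise AssayError("dCAPS design supports single-nucleotide variants only")
    v = variant.position
    if not (0 <= v < len(template)):
        raise AssayError(f"variant position {v} outside template")
    motif = enzyme.motif
    m = len(motif)
    results: list[DcapsPrimer] = []
    seen: set[tuple] = set()

    for orientation in ("rev", "fwd"):
        for gap in range(1, primer_anchor_window + 1):
            if orientation == "rev":
                s = v + gap  # primer footprint [s, s+L), 3' end at s
                if s + primer_length > len(template):
                    continue
                footprint = range(s, s + primer_length)
                protected = set(range(s, s + protected_3prime))
            else:
                e = v - gap + 1  # footprint [e-L, e), 3' end at e-1
                s = e - primer_length
                if s < 0:
                    continue
                footprint = range(s, e)
                protected = set(range(e - protected_3prime, e))
            fp = set(footprint)

            for w in range(v - m + 1, v + 1):  # motif window covering the variant
                if w < 0 or w + m > len(template):
                    continue
                idx_v = v - w
                cutters = [a for a in variant.alleles if a in IUPAC_CODES[motif[idx_v]]]
                if not 0 < len(cutters) < len(variant.alleles):
                    continue  # site must complete for a strict subset of alleles
                ok = True
                subs: dict[int, str] = {}
                for j in range(m):
                    p = w + j
                    if p == v:
                        continue
                    if template.bases[p] in IUPAC_CODES[motif[j]]:
                        continue
                    if p not in fp or p in protected:
                        ok = False
                        break
                    subs[p] = _first_concrete(motif[j])
                if not ok or len(subs) > k_max or v in fp:
                    continue

                key = (orientation, min(footprint), tuple(sorted(subs.items())))
                if key in seen:
                    continue
                seen.add(key)

                top = list(template.bases)
                for p, b in subs.items():
                    top[p] = b
                lo, hi = min(footprint), max(footprint) + 1
                if orientation == "rev":
                    prod_bases = "".join(top[:hi])
                else:
                    prod_bases = "".join(top[lo:])
                patterns: dict[str, FragmentPattern] = {}
                v_local = v if orientation == "rev" else v - lo
                for allele in variant.alleles:
                    pb = prod_bases[:v_local] + allele + prod_bases[v_local + 1 :]
                    patterns[allele] = digest(pb, enzyme)
                wt_pat = patterns[variant.wt].as_multiset()
                if not all(patterns[r].as_multiset() != wt_pat for r in variant.res):
                    continue

                top_footprint = "".join(top[lo:hi])
                orig_top = template.bases[lo:hi]
                if orientation == "rev":
                    original = reverse_complement(orig_top)
                    modified = list(reverse_complement(top_footprint))
                    mm_idx = tuple(sorted((hi - 1) - p for p in subs))
                else:
                    original = orig_top
                    modified = list(top_footprint)
                    mm_idx = tuple(sorted(p - lo for p in subs))
                for i in mm_idx:
                    modified[i] = modified[i].lower()
                results.append(
                    DcapsPrimer(
                        original=original,
                        modified="".join(modified),
                        mismatch_positions=mm_idx,
                        orientation=orientation,
                        binding_start=lo,
                        engineered_enzyme=enzyme,
                        cutting_allele=cutters[0],
                        allele_patterns=patterns,
                    )
                )
    results.sort(key=lambda p: (p.n_mismatches, p.binding_start))
    return results


# ---------------------------------------------------------------------------
# variant table and report I/O


def read_variant_table(path: str | Path) -> list[VariantSpec]:
    """TSV columns: gene, amplicon, position, wt, alt (comma-separated), label."""
    variants = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            variants.append(
                VariantSpec(
                    label=row["label"],
                    position=int(row["position"]),
                    wt=row["wt"],
                    res=tuple(row["alt"].split(",")),
                )
            )
    return variants


def design_report(designs: list[AssayDesign]) -> dict:
    """JSON-serialisable report of candidate designs."""
    out = []
    for d in designs:
        out.append(
            {
                "variant": d.variant.label,
                "enzyme": d.enzyme.name,
                "motif": d.enzyme.motif,
                "discriminates": d.discriminates,
                "allele_patterns": {a: list(p.fragments) for a, p in d.allele_patterns.items()},
                "genotype_bands": {g: list(b) for g, b in d.genotype_patterns.items()},
                "min_visible_bp": d.min_visible_bp,
                "min_separation_frac": d.min_separation_frac,
            }
        )
    return {"designs": out}


def format_design_table(designs: list[AssayDesign]) -> str:
    lines = [f"{'variant':<12}{'enzyme':<10}{'SS bands':<22}{'RR bands':<22}RS bands"]
    for d in designs:
        g = d.genotype_patterns
        lines.append(
            f"{d.variant.label:<12}{d.enzyme.name:<10}"
            f"{'/'.join(map(str, g['SS'])):<22}{'/'.join(map(str, g['RR'])):<22}"
            f"{'/'.join(map(str, g['RS']))}"
        )
    return "\n".join(lines)
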