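"""Synthetic assay fixtures and population simulation.

Real reference sequences for this toolkit's motivating assays live in
GenBank, but every algorithm here is testable without a download: the
fixture generator plants primer binding sites, recognition sites and
variant positions into random sequence at exact coordinates, then
rejection-samples the filler until no accidental extra motif match exists
for any enzyme of interest (verified post hoc by scanning each allele's
PCR product).  ``published_fixtures`` builds the four amplicon geometries
of the diagnostic assay panel this package was written around — the
fragment sizes those assays print on a gel pin down every planted
coordinate.

Variant nucleotide alleles in these fixtures are synthetic toy alleles:
the wild-type base is whatever completes the planted recognition site and
each resistant base destroys it.  Codon frames and flanking context are
not taken from any real accession.

``simulate_population`` draws genotype counts at a chosen allele
frequency and inbreeding coefficient f, with genotype probabilities
p^2 + f p q, 2pq(1 - f), q^2 + f p q (feasible only for
f >= -min(p/q, q/p)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assay import Amplicon, VariantSpec, apply_variant, extract_amplicon
from .enzymes import RestrictionEnzyme, cut_positions, digest, enzyme_by_name, load_enzyme_table
from .popgen import GenotypeCounts, PopGenError
from .sequences import NucleotideSequence, reverse_complement, write_fasta


class FixtureError(RuntimeError):
    """Infeasible fixture geometry (after bounded retries)."""


@dataclass(frozen=True)
class DigestCheck:
    """One verification: PCR with a primer pair, apply an allele, digest.

    ``expected_cuts`` is the exact set of in-sequence top-strand cut
    coordinates the product must show — equality rules out both missing
    planted sites and spurious extra matches.
    """

    enzyme: str
    variant_label: str
    allele: str  # "wt" or a resistant allele string
    fwd: str
    rev: str
    max_mismatch: int
    expected_cuts: frozenset[int]


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of a synthetic template: what goes where, and what must hold."""

    name: str
    length: int
    fwd_primer: str
    rev_primer: str
    fixed_bases: dict[int, str]
    variants: tuple[VariantSpec, ...]
    checks: tuple[DigestCheck, ...]
    seed: int
    max_retries: int = 10000


@dataclass(frozen=True)
class AssayFixture:
    """A generated template plus the assay metadata needed to use it."""

    spec: FixtureSpec
    template: NucleotideSequence
    variants: dict[str, VariantSpec]

    def product(self, fwd: str | None = None, rev: str | None = None, max_mismatch: int = 0) -> Amplicon:
        return extract_amplicon(
            self.template,
            fwd or self.spec.fwd_primer,
            rev or self.spec.rev_primer,
            max_mismatch,
        )

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Emit FASTA plus a JSON sidecar with coordinates and enzymes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / f"{self.spec.name}.fasta"
        sidecar = directory / f"{self.spec.name}.json"
        write_fasta(fasta, self.template)
        meta = {
            "name": self.spec.name,
            "seed": self.spec.seed,
            "length": self.spec.length,
            "fwd_primer": self.spec.fwd_primer,
            "rev_primer": self.spec.rev_primer,
            "variants": [
                {"label": v.label, "position": v.position, "wt": v.wt, "res": list(v.res)}
                for v in self.variants.values()
            ],
            "checks": [
                {
                    "enzyme": c.enzyme,
                    "variant": c.variant_label,
                    "allele": c.allele,
                    "expected_cuts": sorted(c.expected_cuts),
                }
                for c in self.spec.checks
            ],
        }
        sidecar.write_text(json.dumps(meta, indent=1) + "\n")
        return fasta, sidecar


_BASES = np.array(list("ACGT"))


def _run_checks(template: NucleotideSequence, spec: FixtureSpec, enzymes) -> bool:
    variants = {v.label: v for v in spec.variants}
    for chk in spec.checks:
        try:
            amp = extract_amplicon(template, chk.fwd, chk.rev, chk.max_mismatch)
        except Exception:
            return False
        seq = apply_variant(amp, variants[chk.variant_label], chk.allele)
        if set(cut_positions(seq, enzyme_by_name(chk.enzyme, enzymes))) != set(chk.expected_cuts):
            return False
    return True


def make_assay_fixture(
    spec: FixtureSpec, enzymes: list[RestrictionEnzyme] | None = None
) -> AssayFixture:
    """Generate a concrete template satisfying ``spec``.

    Fixed bases (primers, planted sites, variant wild-type bases) are laid
    down first; filler is drawn uniformly and the whole template is
    rejection-sampled until every digest check passes, so the emitted
    sequence provably reproduces the requested cut coordinates with no
    spurious sites.  Deterministic under the spec's seed.
    """
    enzymes = enzymes if enzymes is not None else load_enzyme_table()
    fixed: dict[int, str] = {}

    def fix(pos: int, base: str, what: str) -> None:
        base = base.upper()
        if not (0 <= pos < spec.length):
            raise FixtureError(f"{spec.name}: {what} at {pos} outside template")
        if pos in fixed and fixed[pos] != base:
            raise FixtureError(
                f"{spec.name}: conflicting constraints at {pos} "
                f"({what} wants {base}, already fixed to {fixed[pos]})"
            )
        fixed[pos] = base

    for i, b in enumerate(spec.fwd_primer.upper()):
        fix(i, b, "forward primer")
    rc = reverse_complement(spec.rev_primer.upper())
    off = spec.length - len(rc)
    for i, b in enumerate(rc):
        fix(off + i, b, "reverse primer")
    for pos, b in spec.fixed_bases.items():
        fix(pos, b, "planted base")
    for v in spec.variants:
        for i, b in enumerate(v.wt):
            fix(v.position + i, b, f"variant {v.label} wt")

    free = np.array([i for i in range(spec.length) if i not in fixed], dtype=int)
    arr = np.empty(spec.length, dtype="<U1")
    for pos, b in fixed.items():
        arr[pos] = b
    rng = np.random.default_rng(spec.seed)
    for attempt in range(spec.max_retries):
        arr[free] = _BASES[rng.integers(0, 4, size=free.size)]
        template = NucleotideSequence(spec.name, "".join(arr))
        if _run_checks(template, spec, enzymes):
            return AssayFixture(spec, template, {v.label: v for v in spec.variants})
    raise FixtureError(
        f"{spec.name}: no template satisfying the spec within {spec.max_retries} retries "
        "(geometry may be infeasible)"
    )


# ---------------------------------------------------------------------------
# the published assay geometries

#: Primer pairs of the diagnostic panel (reverse primers 5'->3', bottom strand).
PANEL_PRIMERS = {
    "AChE2": ("TATAAACGTAGTAGTGCCAAGG", "CCGACCATTTTGTCCAAAGC"),
    "nAChR_b1": ("TGCATACGTGGTACGTACATAA", "TGAACGGTTTGCAGTCAAGC"),
    "vgsc": ("CTGCGGGTTACCAAGGACTCTC", "ATCCACCTCGCCGTTTGCAT"),
    "ACCase": ("AATTTGGTGCATACATTGTTGA", "CTGGATCTGCATACATCTCAATA"),
    "ACCase_diag": ("AATTTGGTGCATACATTGTTGA", "GTCTTGGATTAATAGTAGTAGCTACA"),
}


def _ache2_spec(seed: int) -> FixtureSpec:
    fwd, rev = PANEL_PRIMERS["AChE2"]
    a302s = VariantSpec("A302S", 581, "G", ("T",))
    s431f = VariantSpec("S431F", 702, "A", ("C",))
    fixed = {}
    for i, b in enumerate("GCTAGC"):  # Cac8I GCNNGC, cut 581+3 = 584
        fixed[581 + i] = b
    for i, b in enumerate("AATATT"):  # SspI AATATT, cut 699+3 = 702
        fixed[699 + i] = b
    mk = lambda enz, lab, allele, cuts: DigestCheck(
        enz, lab, allele, fwd, rev, 0, frozenset(cuts)
    )
    return FixtureSpec(
        name="AChE2",
        length=897,
        fwd_primer=fwd,
        rev_primer=rev,
        fixed_bases=fixed,
        variants=(a302s, s431f),
        checks=(
            mk("Cac8I", "A302S", "wt", {584}),
            mk("Cac8I", "A302S", "T", set()),
            mk("Cac8I", "S431F", "C", {584}),
            mk("SspI", "S431F", "wt", {702}),
            mk("SspI", "S431F", "C", set()),
            mk("SspI", "A302S", "T", {702}),
        ),
        seed=seed,
    )


def _nachr_spec(seed: int) -> FixtureSpec:
    fwd, rev = PANEL_PRIMERS["nAChR_b1"]
    r81t = VariantSpec("R81T", 314, "C", ("G",))
    fixed = {312 + i: b for i, b in enumerate("GTCTC")}  # BsmAI, top cut 312+6 = 318
    return FixtureSpec(
        name="nAChR_b1",
        length=508,
        fwd_primer=fwd,
        rev_primer=rev,
        fixed_bases=fixed,
        variants=(r81t,),
        checks=(
            DigestCheck("BsmAI", "R81T", "wt", fwd, rev, 0, frozenset({318})),
            DigestCheck("BsmAI", "R81T", "G", fwd, rev, 0, frozenset()),
        ),
        seed=seed,
    )


def _vgsc_spec(seed: int) -> FixtureSpec:
    # the forward primer itself carries a BstEII site cutting at 6 — the
    # constitutive shortest fragment of this assay
    fwd, rev = PANEL_PRIMERS["vgsc"]
    l1014f = VariantSpec("L1014F", 540, "C", ("T",))
    m918 = VariantSpec("M918", 252, "ATG", ("ACG", "TTG", "GTG", "ATA"))
    fixed = {}
    for i, b in enumerate("GGTCACC"):  # BstEII, cut 210+1 = 211
        fixed[210 + i] = b
    for i, b in enumerate("GGTAACC"):  # BstEII, cut 535+1 = 536; 540 is the variant C
        fixed[535 + i] = b
    mk = lambda lab, allele, cuts: DigestCheck(
        "BstEII", lab, allele, fwd, rev, 0, frozenset(cuts)
    )
    return FixtureSpec(
        name="vgsc",
        length=627,
        fwd_primer=fwd,
        rev_primer=rev,
        fixed_bases=fixed,
        variants=(l1014f, m918),
        checks=(
            mk("L1014F", "wt", {6, 211, 536}),
            mk("L1014F", "T", {6, 211}),
            mk("M918", "ACG", {6, 211, 536}),
            mk("M918", "TTG", {6, 211, 536}),
            mk("M918", "GTG", {6, 211, 536}),
            mk("M918", "ATA", {6, 211, 536}),
        ),
        seed=seed,
    )


def _accase_spec(seed: int) -> FixtureSpec:
    # dCAPS: the diagnostic reverse primer rewrites coordinate 105 to C
    # (its lower-case base), completing MwoI GCNNNNNNNGC at [95, 106) on
    # the wild-type allele only; top cut 95+7 = 102 -> fragments 102 + 24.
    fwd, rev = PANEL_PRIMERS["ACCase"]
    diag = PANEL_PRIMERS["ACCase_diag"][1]
    a2226v = VariantSpec("A2226V", 96, "C", ("T",))
    binding = list(reverse_complement(diag))
    binding[5] = "A"  # template base the engineered primer mismatches (coord 105)
    fixed = {100 + i: b for i, b in enumerate(binding)}
    fixed[95] = "G"
    mk = lambda rv, mm, allele, cuts: DigestCheck(
        "MwoI", "A2226V", allele, fwd, rv, mm, frozenset(cuts)
    )
    return FixtureSpec(
        name="ACCase_dCAPS",
        length=150,
        fwd_primer=fwd,
        rev_primer=rev,
        fixed_bases=fixed,
        variants=(a2226v,),
        checks=(
            mk(diag, 1, "wt", {102}),   # engineered product, wt allele: cut
            mk(diag, 1, "T", set()),    # engineered product, resistant: uncut
            mk(rev, 0, "wt", set()),    # unmodified 150 bp product: no site at all
            mk(rev, 0, "T", set()),
        ),
        seed=seed,
    )


def published_fixtures(seed: int = 0) -> dict[str, AssayFixture]:
    """Generate the four diagnostic-panel fixtures (five assays).

    Per-assay seeds are derived from ``seed`` so fixtures are independent
    and individually reproducible.
    """
    specs = {
        "AChE2": _ache2_spec(seed * 4 + 1),
        "nAChR_b1": _nachr_spec(seed * 4 + 2),
        "vgsc": _vgsc_spec(seed * 4 + 3),
        "ACCase_dCAPS": _accase_spec(seed * 4 + 4),
    }
    return {name: make_assay_fixture(sp) for name, sp in specs.items()}


# ---------------------------------------------------------------------------
# population simulation


@dataclass(frozen=True)
class PopulationSimSpec:
    """Sample N genotypes at allele frequency fR with inbreeding f."""

    N: int
    fR: float
    f: float
    seed: int
    population: str = "sim"

    def probabilities(self) -> tuple[float, float, float]:
        p, q, f = self.fR, 1.0 - self.fR, self.f
        probs = (p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q)
        if min(probs) < -1e-12:
            bound = -min(p / q if q else np.inf, q / p if p else np.inf)
            raise PopGenError(
                f"infeasible inbreeding f={f:g} at fR={p:g}: genotype probabilities "
                f"must be non-negative, requires f >= {bound:.4g}"
            )
        return tuple(max(0.0, x) for x in probs)


def simulate_population(spec: PopulationSimSpec) -> GenotypeCounts:
    """One multinomial draw of (n_RR, n_RS, n_SS); deterministic under seed."""
    if spec.N < 1:
        raise PopGenError("N >= 1 required")
    rng = np.random.default_rng(spec.seed)
    n_rr, n_rs, n_ss = rng.multinomial(spec.N, spec.probabilities())
    return GenotypeCounts(spec.population, int(n_rr), int(n_rs), int(n_ss))


def simulate_populations(
    spec: PopulationSimSpec, replicates: int
) -> list[GenotypeCounts]:
    """Independent replicate draws, seeds derived from the spec seed."""
    rng = np.random.default_rng(spec.seed)
    probs = spec.probabilities()
    draws = rng.multinomial(spec.N, probs, size=replicates)
    return [
        GenotypeCounts(f"{spec.population}_{i}", int(a), int(h), int(c))
        for i, (a, h, c) in enumerate(draws)
    ]
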