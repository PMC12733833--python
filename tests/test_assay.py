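"""CAPS evaluation, ranking and dCAPS primer engineering."""

import numpy as np
import pytest

from capskit import (
    AssayError,
    NucleotideSequence,
    VariantSpec,
    apply_variant,
    design_caps,
    design_dcaps,
    digest,
    evaluate_assay,
    extract_amplicon,
)
from capskit.fixtures import PANEL_PRIMERS
from capskit.sequences import IUPAC_CODES, reverse_complement

FWD18 = "ACGTACGTACGTACGTAC"
REV18 = "TGCATGCATGCATGCATG"


def _toy_template(middle: str, flank_left="GG", flank_right="CC") -> NucleotideSequence:
    bases = flank_left + FWD18 + middle + reverse_complement(REV18) + flank_right
    return NucleotideSequence("toy", bases)


# ---------------------------------------------------------------------------
# in-silico PCR


def test_extract_amplicon_end_to_end_length():
    t = _toy_template("A" * 24)
    amp = extract_amplicon(t, FWD18, REV18)
    assert amp.expected_length == 60
    assert amp.start == 2
    assert amp.product.bases == t.bases[2:62]


def test_extract_amplicon_error_cases():
    t = _toy_template("A" * 24)
    with pytest.raises(AssayError, match="not found"):
        extract_amplicon(t, "T" * 18, REV18)
    with pytest.raises(AssayError, match="opposite strand"):
        extract_amplicon(t, reverse_complement(FWD18), REV18)
    two_fwd = NucleotideSequence("t2", FWD18 + "AAAA" + FWD18 + "A" * 10 + reverse_complement(REV18))
    with pytest.raises(AssayError, match="not specific"):
        extract_amplicon(two_fwd, FWD18, REV18)
    swapped = NucleotideSequence("t3", reverse_complement(REV18) + "A" * 20 + FWD18)
    with pytest.raises(AssayError, match="inconsistently"):
        extract_amplicon(swapped, FWD18, REV18)
    with pytest.raises(AssayError, match=">= 15"):
        extract_amplicon(t, "ACGT", REV18)


def test_mismatch_primer_overwrites_template_base():
    t = _toy_template("A" * 24)
    fwd_mm = "ACGTACGTTCGTACGTAC"  # one internal mismatch vs FWD18
    amp = extract_amplicon(t, fwd_mm, REV18, max_mismatch=1)
    assert amp.product.bases[:18] == fwd_mm  # primer-encoded, not template
    assert amp.mismatch_positions == (8,)
    with pytest.raises(AssayError):
        extract_amplicon(t, fwd_mm, REV18, max_mismatch=0)


def test_published_primer_pairs_give_published_lengths(panel):
    expected = {"AChE2": 897, "nAChR_b1": 508, "vgsc": 627, "ACCase_dCAPS": 150}
    for name, length in expected.items():
        assert panel[name].product().expected_length == length
    diag = panel["ACCase_dCAPS"].product(
        rev=PANEL_PRIMERS["ACCase_diag"][1], max_mismatch=1
    )
    assert diag.expected_length == 126


# ---------------------------------------------------------------------------
# variants


def test_apply_variant_wt_is_identity_on_wt_template(panel):
    amp = panel["AChE2"].product()
    v = panel["AChE2"].variants["S431F"]
    assert apply_variant(amp, v, "wt").bases == amp.product.bases


def test_apply_variant_validation():
    v = VariantSpec("x", 2, "A", ("G",))
    seq = NucleotideSequence("s", "AAAAA")
    assert apply_variant(seq, v, "G").bases == "AAGAA"
    with pytest.raises(AssayError):
        apply_variant(seq, v, "T")  # unknown allele
    with pytest.raises(AssayError):
        VariantSpec("x", 0, "A", ("AG",))  # length mismatch
    with pytest.raises(AssayError):
        VariantSpec("x", 0, "A", ("A",))  # identical to wt
    with pytest.raises(AssayError):
        apply_variant(seq, VariantSpec("y", 9, "A", ("G",)), "wt")  # outside


def test_codon_variant_substitution():
    v = VariantSpec("M918", 3, "ATG", ("ACG", "TTG"))
    seq = NucleotideSequence("s", "CCCATGCCC")
    assert apply_variant(seq, v, "TTG").bases == "CCCTTGCCC"


# ---------------------------------------------------------------------------
# assay evaluation


def test_s431f_sspi_genotype_band_sets(panel, enzymes):
    amp = panel["AChE2"].product()
    d = evaluate_assay(amp, panel["AChE2"].variants["S431F"], enzymes["SspI"])
    assert d.discriminates
    assert d.genotype_patterns["SS"] == (702, 195)
    assert d.genotype_patterns["RR"] == (897,)
    assert d.genotype_patterns["RS"] == (897, 702, 195)


def test_l1014f_bstEII_discriminates_with_invisible_fragment(panel, enzymes):
    amp = panel["vgsc"].product()
    d = evaluate_assay(amp, panel["vgsc"].variants["L1014F"], enzymes["BstEII"])
    assert d.discriminates
    assert d.allele_patterns["C"].fragments == (325, 205, 91, 6)
    assert d.allele_patterns["T"].fragments == (416, 205, 6)
    # the 6 bp fragment is flagged unresolvable and never required on a gel
    assert d.genotype_patterns["SS"] == (325, 205, 91)
    assert d.genotype_patterns["RR"] == (416, 205)


def test_variant_outside_any_site_does_not_discriminate(panel, enzymes):
    amp = panel["vgsc"].product()
    d = evaluate_assay(amp, panel["vgsc"].variants["M918"], enzymes["BstEII"])
    assert not d.discriminates


def test_heterozygote_bands_are_union_of_homozygotes(panel, enzyme_library):
    for fx in panel.values():
        amp = fx.product()
        for v in fx.variants.values():
            for enz in enzyme_library:
                d = evaluate_assay(amp, v, enz)
                for r in v.res:
                    ss = set(d.per_res_patterns[r]["SS"])
                    rr = set(d.per_res_patterns[r]["RR"])
                    assert set(d.per_res_patterns[r]["RS"]) == ss | rr


def test_discrimination_symmetric_under_allele_swap(panel, enzymes):
    fx = panel["AChE2"]
    amp = fx.product()
    v = fx.variants["S431F"]
    swapped = VariantSpec(v.label, v.position, v.res[0], (v.wt,))
    d1 = evaluate_assay(amp, v, enzymes["SspI"])
    d2 = evaluate_assay(amp, swapped, enzymes["SspI"])
    assert d1.discriminates == d2.discriminates


# ---------------------------------------------------------------------------
# CAPS design


def test_design_caps_toy_snp_creating_sspi(enzyme_library):
    middle = "GGCC" + "AATATT" + "GGCCGGCCGGCCGGCCGGCC"
    t = _toy_template(middle)
    amp = extract_amplicon(t, FWD18, REV18)
    pos = amp.product.bases.index("AATATT") + 3
    v = VariantSpec("snp", pos, "A", ("G",))
    designs = design_caps(amp, v, enzyme_library, min_visible_bp=5)
    assert "SspI" in [d.enzyme.name for d in designs]


def test_design_caps_snp_away_from_motifs_is_empty(enzyme_library):
    t = _toy_template("A" * 30)
    amp = extract_amplicon(t, FWD18, REV18)
    v = VariantSpec("snp", 25, "A", ("T",))
    assert design_caps(amp, v, enzyme_library) == []


def test_design_caps_finds_published_s431f_assay(panel, enzyme_library):
    fx = panel["AChE2"]
    designs = design_caps(fx.product(), fx.variants["S431F"], enzyme_library)
    assert "SspI" in [d.enzyme.name for d in designs]


def test_design_caps_multiallelic_m918_has_no_assay(panel, enzyme_library):
    """A single enzyme must separate every resistant codon from wt; none does."""
    fx = panel["vgsc"]
    assert design_caps(fx.product(), fx.variants["M918"], enzyme_library) == []


def test_design_caps_empty_library_rejected(panel):
    fx = panel["AChE2"]
    with pytest.raises(AssayError):
        design_caps(fx.product(), fx.variants["S431F"], [])


def _oracle_discriminators(product, variant, enzymes, min_visible):
    """Exhaustive two-allele digestion using brute-force scanning only."""
    names = []
    for enz in enzymes:
        motif = enz.motif
        m = len(motif)

        def cuts(bases):
            out = set()
            n = len(bases)
            rc = reverse_complement(motif)
            for s in range(n - m + 1):
                if all(bases[s + j] in IUPAC_CODES[motif[j]] for j in range(m)):
                    c, bc = s + enz.cut_offset_top, s + enz.cut_offset_bottom
                    if 0 < c < n and 0 <= bc <= n:
                        out.add(c)
                if all(bases[s + j] in IUPAC_CODES[rc[j]] for j in range(m)):
                    c, bc = s + m - enz.cut_offset_bottom, s + m - enz.cut_offset_top
                    if 0 < c < n and 0 <= bc <= n:
                        out.add(c)
            return out

        def bands(bases):
            bounds = [0, *sorted(cuts(bases)), len(bases)]
            return {b - a for a, b in zip(bounds, bounds[1:]) if b - a >= min_visible}

        wt = apply_variant(product, variant, "wt").bases
        ok = True
        for r in variant.res:
            res = apply_variant(product, variant, r).bases
            if bands(wt) == bands(res):
                ok = False
                break
        if ok:
            names.append(enz.name)
    return sorted(names)


def test_design_caps_matches_exhaustive_oracle_on_random_amplicons(enzyme_library):
    rng = np.random.default_rng(11)
    n_checked = 0
    for _ in range(60):
        n = int(rng.integers(60, 300))
        bases = "".join(rng.choice(list("ACGT"), size=n))
        product = NucleotideSequence("r", bases)
        pos = int(rng.integers(0, n))
        wt = bases[pos]
        res = rng.choice([b for b in "ACGT" if b != wt])
        v = VariantSpec("snp", pos, wt, (str(res),))
        got = sorted(
            d.enzyme.name
            # disable co-migration collapse so the oracle rule is identical
            for d in design_caps(product, v, enzyme_library, min_visible_bp=20,
                                 min_separation_frac=0.0)
        )
        assert got == _oracle_discriminators(product, v, enzyme_library, 20)
        n_checked += 1
    assert n_checked == 60


# ---------------------------------------------------------------------------
# dCAPS


def test_design_dcaps_recovers_published_accase_primer(panel, enzymes):
    fx = panel["ACCase_dCAPS"]
    primers = design_dcaps(
        fx.template, fx.variants["A2226V"], enzymes["MwoI"],
        primer_anchor_window=10, k_max=2, protected_3prime=3, primer_length=26,
    )
    modified = {p.modified for p in primers}
    assert PANEL_PRIMERS["ACCase_diag"][1][:20] + "g" + "CTACA" in modified
    hit = next(p for p in primers if p.binding_start == 100)
    assert hit.n_mismatches == 1
    assert hit.mismatch_positions == (20,)
    assert hit.cutting_allele == "C"  # the wild-type (susceptible) allele cuts
    assert hit.allele_patterns["C"].fragments == (102, 24)
    assert hit.allele_patterns["T"].fragments == (126,)


def test_design_dcaps_k0_returns_only_mismatch_free_primers(panel, enzymes):
    fx = panel["ACCase_dCAPS"]
    primers = design_dcaps(fx.template, fx.variants["A2226V"], enzymes["MwoI"], k_max=0)
    assert all(p.n_mismatches == 0 for p in primers)


def test_design_dcaps_protected_3prime_window(panel, enzymes):
    fx = panel["ACCase_dCAPS"]
    for protected in (3, 6):
        for p in design_dcaps(
            fx.template, fx.variants["A2226V"], enzymes["MwoI"],
            protected_3prime=protected,
        ):
            assert all(i < len(p.modified) - 0 for i in p.mismatch_positions)
            # 3' end of the primer is its last character (5'->3'); engineered
            # bases must stay clear of the terminal window
            assert all(i <= len(p.modified) - 1 - protected for i in p.mismatch_positions)


def test_dcaps_zero_mismatch_reduces_to_caps(enzymes):
    """Primers needing no mismatch are plain CAPS through primer placement."""
    from capskit import cut_positions

    rng = np.random.default_rng(3)
    v = VariantSpec("snp", 30, "T", ("C",))
    while True:  # deterministic rejection sampling of a clean toy template
        bases = "".join(rng.choice(list("ACGT"), size=70))
        t = NucleotideSequence("t", bases[:25] + "AATATT" + bases[31:])
        if (
            cut_positions(apply_variant(t, v, "wt"), enzymes["SspI"]) == [28]
            and cut_positions(apply_variant(t, v, "C"), enzymes["SspI"]) == []
        ):
            break
    primers = design_dcaps(
        t, v, enzymes["SspI"], k_max=0, primer_length=20, primer_anchor_window=8
    )
    assert primers
    for p in primers:
        assert p.n_mismatches == 0 and p.modified == p.original
        end = p.binding_start + len(p.modified)
        if p.orientation == "rev":
            product, shifted = t.bases[:end], v
        else:
            product = t.bases[p.binding_start :]
            shifted = VariantSpec(v.label, v.position - p.binding_start, v.wt, v.res)
        for allele in v.alleles:
            raw = apply_variant(NucleotideSequence("x", product), shifted, allele)
            assert digest(raw, enzymes["SspI"]).fragments == p.allele_patterns[allele].fragments
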