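"""Engineer a dCAPS mismatch primer for a SNP with no natural restriction site.

The ACCase A2226V amplicon carries no MwoI site on either allele, so no
plain CAPS assay exists.  A reverse primer with one deliberate mismatch
(lower case) rewrites a base next to the SNP so that MwoI's degenerate
motif GCNNNNNNNGC is completed by the susceptible allele's base only:
the wild-type product cuts (two bands), the resistant product stays whole.
"""

from capskit import design_dcaps, enzyme_by_name, published_fixtures

fx = published_fixtures(seed=0)["ACCase_dCAPS"]
primers = design_dcaps(
    fx.template,
    fx.variants["A2226V"],
    enzyme_by_name("MwoI"),
    primer_anchor_window=10,
    k_max=2,
    protected_3prime=3,
    primer_length=26,
)

print(f"{len(primers)} candidate primer(s); best (fewest mismatches) first:\n")
for p in primers[:5]:
    patterns = ", ".join(f"{allele}: {pat}" for allele, pat in p.allele_patterns.items())
    print(f"  {p.orientation} primer 5'-{p.modified}-3'")
    print(f"    mismatches at primer position(s) {p.mismatch_positions}; "
          f"cutting allele {p.cutting_allele!r}; {patterns}")
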