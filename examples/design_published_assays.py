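"""Evaluate the five diagnostic-panel CAPS/dCAPS assays on synthetic fixtures.

Builds the four published-geometry amplicon fixtures, digests each allele's
PCR product with the assay enzyme and prints per-genotype band patterns.
Each line shows the bands a gel would resolve for homozygous-susceptible
(SS), heterozygous (RS) and homozygous-resistant (RR) aphids; an assay
"discriminates" when SS and RR lanes look different.
"""

from capskit import evaluate_assay, enzyme_by_name, published_fixtures
from capskit.fixtures import PANEL_PRIMERS

panel = published_fixtures(seed=0)
assays = [
    ("AChE2", "A302S", "Cac8I", None, 0),
    ("nAChR_b1", "R81T", "BsmAI", None, 0),
    ("vgsc", "L1014F", "BstEII", None, 0),
    ("ACCase_dCAPS", "A2226V", "MwoI", PANEL_PRIMERS["ACCase_diag"][1], 1),
    ("AChE2", "S431F", "SspI", None, 0),
]

for name, variant_label, enzyme_name, rev, mm in assays:
    fx = panel[name]
    amp = fx.product(rev=rev, max_mismatch=mm) if rev else fx.product()
    design = evaluate_assay(amp, fx.variants[variant_label], enzyme_by_name(enzyme_name))
    g = design.genotype_patterns
    print(
        f"{variant_label:>7} + {enzyme_name:<6} ({amp.expected_length:>3} bp product)  "
        f"SS: {'/'.join(map(str, g['SS'])):<12} "
        f"RS: {'/'.join(map(str, g['RS'])):<16} "
        f"RR: {'/'.join(map(str, g['RR'])):<8} "
        f"discriminates={design.discriminates}"
    )

# the M918T/L/V/I site has four resistant codons; no single library enzyme
# separates all of them from wild type, so genotyping falls back to sequencing
from capskit import design_caps, load_enzyme_table

vgsc = panel["vgsc"]
hits = design_caps(vgsc.product(), vgsc.variants["M918"], load_enzyme_table())
print(f"\nM918T/L/V/I CAPS designs found: {len(hits)} (sequencing required)")
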