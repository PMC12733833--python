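"""Call genotypes from band sizes read off a gel.

Uses the S431F/SspI assay: the susceptible allele's 897 bp product cuts
into 702 + 195 bp, the resistant allele stays undigested, and a
heterozygote shows all three bands.  Band estimates within 10% of the
expected size still call; an unexplained lane is reported ambiguous.
"""

from capskit import ObservedLanes, call_genotype, enzyme_by_name, evaluate_assay, published_fixtures

fx = published_fixtures(seed=0)["AChE2"]
design = evaluate_assay(fx.product(), fx.variants["S431F"], enzyme_by_name("SspI"))

lanes = [
    ObservedLanes("lane1", (897,)),            # resistant homozygote
    ObservedLanes("lane3", (900, 710, 200)),   # heterozygote, sloppy size estimates
    ObservedLanes("lane5", (702, 195)),        # susceptible homozygote
    ObservedLanes("lane7", (500,)),            # matches nothing
]
for lane in lanes:
    call = call_genotype(lane, design, tolerance_frac=0.10)
    print(f"{lane.sample_id}: bands {lane.bands} -> {call.call}")
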