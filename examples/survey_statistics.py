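"""Population-survey statistics for a genotyped resistance mutation.

Takes the four-region S431F genotype counts, prints the survey table
(genotype percentages, resistant-allele frequency fR as %, sample size N)
and, for the one region with an adequate sample, the inbreeding
coefficient F_IS and the exact Hardy-Weinberg probability test.  A
negative F_IS means heterozygote excess; the pooled column reports
frequencies only (testing HWE on pooled samples invites a Wahlund
artefact).
"""

from capskit import GenotypeCounts, fis_weir_cockerham, hwe_exact_test, survey_table

regions = [
    GenotypeCounts("Argolida", 0, 1, 10),
    GenotypeCounts("Chania", 2, 34, 6),
    GenotypeCounts("Heraklion", 0, 8, 4),
    GenotypeCounts("Messinia", 0, 7, 0),
]

print(survey_table(regions).to_string(), "\n")

chania = regions[1]
ho, hs, fis = fis_weir_cockerham(chania)
p = hwe_exact_test(chania)
print(f"Chania (N={chania.N}): Ho={ho:.3f}  Hs={hs:.3f}  Fis={fis:.3f}  exact HWE p={p:.2e}")
print("-> strong heterozygote excess; significant deviation from HWE (p < 0.001)")
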