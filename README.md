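# capskit

Design and score PCR-RFLP (CAPS/dCAPS) molecular diagnostics for
target-site insecticide-resistance mutations, and analyse the resulting
population surveys.

Resistance to most major insecticide classes in aphids and other pests is
often caused by single point mutations in the insecticide's target
protein — e.g. *kdr* L1014F and super-*kdr* M918T/L/V/I in the
voltage-gated sodium channel (pyrethroids), S431F in acetylcholinesterase
(dimethyl-carbamates such as pirimicarb), R81T in the nicotinic
acetylcholine receptor β1 subunit (neonicotinoids) and A2226V in the
ACCase carboxyltransferase domain (spirotetramat).  Monitoring programmes
need cheap assays that genotype hundreds of field-collected individuals
without sequencing.  A **CAPS** assay exploits a restriction enzyme whose
recognition site is created or destroyed by the mutation, so wild-type
and resistant PCR products give different gel band patterns; when no such
enzyme exists, a **dCAPS** primer with deliberate mismatches engineers a
diagnostic site next to the SNP.  `capskit` automates the whole workflow
for molecular entomologists and resistance-monitoring labs:

* in-silico restriction digestion with degenerate IUPAC motifs and
  strand-specific cut offsets (including type IIS outside cutters),
* in-silico PCR, CAPS assay evaluation/ranking and dCAPS mismatch-primer
  engineering,
* genotype calling from observed band sizes and per-population tallies,
* biallelic population genetics: allele frequencies, observed/expected
  heterozygosity, the inbreeding coefficient F_IS, and the exact
  Hardy–Weinberg probability test,
* seeded synthetic fixtures and population simulators so everything is
  testable offline.

## The statistics at the core

For genotype counts (n_RR, n_RS, n_SS), N = n_RR + n_RS + n_SS and
resistant-allele frequency p = (2·n_RR + n_RS)/2N:

* **F_IS** (sample-size-corrected, single population):
  Ho = n_RS/N,  Hs = N/(N−1)·(1 − p² − q² − Ho/2N),  F_IS = 1 − Ho/Hs.
  Negative values mean heterozygote excess.
* **Exact HWE probability test** (Levene conditional distribution): with
  allele counts n_R, n_S fixed, P(h) = N!/(n_RR! h! n_SS!) · 2^h ·
  n_R! n_S!/(2N)! over every heterozygote count h with the parity of n_R;
  the p-value sums P over all configurations no more probable than the
  observed one (ties included).  Full enumeration, no Monte Carlo.

## Worked example

```python
from capskit import GenotypeCounts, fis_weir_cockerham, hwe_exact_test, survey_table

regions = [
    GenotypeCounts("Argolida", 0, 1, 10),
    GenotypeCounts("Chania", 2, 34, 6),
    GenotypeCounts("Heraklion", 0, 8, 4),
    GenotypeCounts("Messinia", 0, 7, 0),
]
print(survey_table(regions))
ho, hs, fis = fis_weir_cockerham(regions[1])
print(round(fis, 3), hwe_exact_test(regions[1]))
```

prints

```
    Argolida  Chania  Heraklion  Messinia  Total
RR       0.0     4.8        0.0       0.0    2.8
RS       9.1    81.0       66.7     100.0   69.4
SS      90.9    14.3       33.3       0.0   27.8
fR       4.5    45.2       33.3      50.0   37.5
N       11.0    42.0       12.0       7.0   72.0
-0.627 0.00010208183580357704
```

— genotype percentages and the resistant-allele frequency fR (as %) per
region, a pooled column (frequencies only: testing HWE on pooled samples
invites a Wahlund artefact), and for the largest sample a strong
heterozygote excess (F_IS = −0.627) with a highly significant exact-test
deviation from Hardy–Weinberg (p ≈ 1×10⁻⁴).

The `examples/` directory holds one short script per capability
(assay evaluation, dCAPS primer engineering, gel-lane genotype calling,
survey statistics, simulation-based calibration); each prints the numbers
it computes and a line on what they mean.  A thin CLI mirrors the
library: `capskit scan | digest | design | dcaps | genotype | popgen |
simulate | fixtures` (see `capskit --help`).

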