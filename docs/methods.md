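# Methods

## Restriction model and coordinates

An enzyme is a degenerate IUPAC motif plus two cut offsets, one per
strand, both counted in phosphodiester-bond coordinates from the 5′ end of
the top-strand motif match.  Offsets come from REBASE-style notation
(`GCN^NGC`, `G^GTNACC`, `AAT^ATT`, `GCNNNNN^NNGC`, `GTCTC(1/5)`); the
caret dialect is restricted to palindromic motifs, where the bottom-strand
offset is the mirror of the top one, and the `(t/b)` dialect covers
type IIS outside cutters.  Parsed offsets are cross-checked in the test
suite against Bio.Restriction's characteristics, and site scanning and
digestion are cross-checked against both a test-every-offset brute-force
scanner and Bio.Restriction's `search` on random templates — the engine
itself never delegates to either.

Coordinates are 0-based, half-open; 1-based numbers appear only in
human-readable CLI output.  Bottom-strand sites are found by matching the
motif's reverse complement on the top strand; for palindromic motifs the
two orientations of a locus are one physical site and are deduplicated.

Fragment sizes are computed from top-strand cuts only: on a native gel a
few nucleotides of overhang do not move a band.  A site contributes a
fragment boundary only when **both** strand cuts land on the template —
an outside cutter whose distal cut falls past the end nicks one strand
and does not linearise; this matches Bio.Restriction's behaviour and is
exercised by the cross-check tests.  Duplicate cut positions merge, so
zero-length fragments cannot arise.  Linear templates only; circular
digestion is out of scope, as are methylation sensitivity, star activity
and partial digestion.

Ambiguity codes in the *input* sequence are rejected by default (the
intended templates are Sanger-resolved amplicons); opt-in `optimistic` /
`pessimistic` modes count an ambiguous base as a match when the expansion
sets overlap, or only when the base's set is contained in the motif
code's, respectively.

## In-silico PCR and assay evaluation

A product runs from the forward primer's 5′ end through the reverse
primer's 5′ end inclusive (end-to-end convention; reverse primers are
given 5′→3′ on the bottom strand).  Primer-encoded bases overwrite the
template in the product, as in real PCR — this is what makes dCAPS work.
Primer location failures distinguish not-found (with an opposite-strand
hint), non-specific (multiple sites) and inconsistent orientation.

An assay evaluation digests every allele's product and compares
*resolvable* band sets: fragments below `min_visible_bp` (default 20 bp;
configurable because gel percentage governs what is visible — a 24 bp
diagnostic fragment needs a high-percentage gel) are flagged
unresolvable, and two bands closer than `min_separation_frac` (default 5%
of the larger; agarose resolution, chosen here as a pragmatic default) are
treated as co-migrating.  The heterozygote's band set is the union of the
homozygote sets.  An assay *discriminates* when the SS and RR resolvable
sets differ — for multi-allelic sites (e.g. four resistant codons at one
residue) every resistant variant must differ from wild type, which is why
such sites frequently admit no single-enzyme assay and fall back to
sequencing; the toolkit reports that honestly as an empty design list.
Ranking is lexicographic: more distinguishing bands, then the largest
smallest-informative fragment, then fewer total fragments.

## dCAPS primer enumeration

Candidate primers anchor with their 3′ end within `primer_anchor_window`
nucleotides of the SNP without covering it (the diagnostic base must come
from the genome, never from the primer).  For every motif window spanning
the SNP, the needed rewrites inside the primer footprint are computed;
candidates with more than `k_max` mismatches, any mismatch within the
`protected_3prime` terminal window (a 3′-terminal mismatch aborts
extension), or a window that completes for all or none of the alleles are
discarded.  Survivors are verified by digesting both allele products;
`k_max = 0` degenerates to plain CAPS through primer placement.  Rewritten
bases take the alphabetically first base of the motif code's expansion,
which keeps enumeration deterministic.

## Genotype calling

Observed lanes match a genotype when every expected resolvable band has an
observed partner within `tolerance_frac` (default 10%, reflecting gel
size-estimation error) and vice versa; anything matching zero or several
genotypes is ambiguous and excluded from N in the tallies.  Bands the
design flags unresolvable are dropped from the expectation first.

## Population statistics

F_IS uses the sample-size-corrected single-population estimator
Ho = n_RS/N, Hs = (N/(N−1))(1 − p² − q² − Ho/2N), F_IS = 1 − Ho/Hs,
matching what standard survey software reports for one population; the
naive 1 − Ho/2pq is exposed separately and clearly labelled.  Monomorphic
samples return an undefined (None) F_IS, never 0.

The exact Hardy–Weinberg probability test enumerates the full Levene
conditional distribution of the heterozygote count given the allele
counts, in log-factorial arithmetic; the p-value includes ties
(probabilities equal to the observed configuration's, compared with a
1e−12 relative tolerance to absorb float noise).  Enumeration is O(N)
configurations, so Monte Carlo is unnecessary at survey scale; the
distribution's sum is unit-tested to 1 ± 1e−12 up to N = 1000.

Survey tables print genotype percentages and fR to one decimal.  The
pooled column carries frequencies only: pooling differentiated
populations depresses heterozygosity (Wahlund effect), so pooled HWE/F_IS
are computed only under an explicit force flag that emits a warning.
Counts can be reconstructed from printed percentage tables by
nearest-integer of pct × N with a round-trip consistency check.

## Synthetic fixtures and simulation

The fixture generator lays down primers, planted recognition sites and
variant wild-type bases at exact coordinates, fills the rest with uniform
random bases, and rejection-samples (cap 10,000 tries) until every digest
check passes: each allele's product must show exactly the requested cut
coordinates, which simultaneously proves the planted sites exist and that
no spurious motif match arose anywhere, on either strand.  Generation is
deterministic under the spec seed and byte-identical on rerun.

`published_fixtures` builds the four amplicons of the diagnostic panel
(897 bp AChE2 carrying A302S/Cac8I and S431F/SspI; 508 bp nAChR β1 with
R81T/BsmAI; 627 bp vgsc with L1014F/BstEII and the multi-allelic M918
codon; 150 bp ACCase with the A2226V/MwoI dCAPS design).  Their planted
coordinates are fully determined by the assays' printed fragment sizes;
notably, the vgsc forward primer itself contains a BstEII site, which is
the origin of that assay's constitutive 6 bp fragment, and the ACCase
dCAPS reverse primer's single lower-case mismatch maps to the final C of
the MwoI motif.  Variant alleles in fixtures are synthetic toys — the
wild-type base completes the planted site, each resistant base breaks it —
since no real codon context is bundled.  What fixtures do **not** emulate:
real flanking genomic sequence, polymorphism outside the assayed SNP,
heteroduplex or partial-digestion artefacts, and gel-image noise; passing
tests therefore validate the algorithms and the published geometries, not
wet-lab robustness on new field material.

Population samples are single multinomial draws with inbreeding-adjusted
genotype probabilities p² + f·p·q, 2pq(1 − f), q² + f·p·q, feasible for
f ≥ −min(p/q, q/p) (violations raise an error citing the bound).
Calibration tests use 1,000 replicates at the survey-like regime (N = 42,
fR = 0.452, f = −0.627), recovering mean F_IS within ±0.05, and 2,000
null draws at fR = 0.3, N = 50 (a representative null regime chosen once)
for the exact test's size, which stays below 0.07 at α = 0.05 — the exact
test is conservative by construction.

## Numerical and design notes

* Problem sizes in tests (500 random templates ≤ 2 kb for scanner
  equivalence, 120 toy amplicons ≤ 300 bp for designer equivalence,
  1,000/2,000 simulation replicates) were chosen as the package's own
  test budget; all are full-strength, none are Monte Carlo stand-ins for
  an exact check.
* The band co-migration rule treats exactly equal lengths as co-migrating
  even at separation fraction 0, making that setting an exact multiset
  comparison.
* Accession fetching (`capskit fetch-accession`, Bio.Entrez) is an
  opt-in network helper for validating designs against real GenBank
  records; nothing in the library or test suite requires it.

## Known limitations

Substitution variants only (no indels); biallelic loci only in the
population module (no multi-locus or F_ST machinery); thermodynamic
primer properties (Tm, dimers, hairpins) are out of scope — primers are
taken as given, as in the assays this package generalises.
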