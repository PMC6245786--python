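# Methods

## Study design emulated by the simulator

The simulator models the standard mapping-by-sequencing design for a fully
penetrant recessive allele. Two F1 parents are heterozygous at every
marker, each carrying one haplotype from the mutagenized strain (which
carries the causal allele and, by construction, the alternate allele at
every marker) and one from the mapping strain. F2 offspring are produced
by two independent meioses; the offspring homozygous for the causal allele
form the mutant pool, any others the sibling pool (phenotype = genotype:
full penetrance, no misclassification). Pool sizes are filled from
successive simulated clutches; unreachable pool sizes raise an error after
a bounded number of clutches.

Meiosis uses the Haldane map function, `r = (1 − e^(−2d))/2`, with
independent crossover events per marker interval (no interference). Map
distances come from a uniform rate of **2 cM/Mb**, the approximate
genome-wide average for zebrafish (≈2700 cM over ≈1.37 Gb). Marker
positions are drawn uniformly per chromosome at the configured density.

Pooled sequencing is modelled per marker and pool: read depth is
Poisson with mean 9 (mutant pool) or 8 (sibling pool), matching shallow
whole-genome pool sequencing; each read reports the alternate allele with
probability `f(1−2e) + e`, where `f` is the pool allele frequency and
`e = 0.01` the per-read miscall probability. Each pool is then genotyped
as **one pseudo-diploid sample**: genotype likelihoods for 0/0, 0/1, 1/1
come from a binomial read model with per-read alternate probabilities
`e`, `0.5`, `1−e`; the call is the likelihood argmax and GQ the
phred-scaled ratio of best to second-best likelihood, capped at 99 (zero
depth gives a missing call with GQ 0). A homozygous pseudo-diploid call
therefore means "pool allele frequency near 1", which is exactly the
signal the homozygosity statistics consume.

Defaults: 25 chromosomes × 50 Mb, 2 markers/Mb, causal site
chr13:29,288,858 A>T, 40 mutant + 40 sibling embryos. The pool size is a
free design choice (typical clutch-scale sorting yields tens of embryos
per pool); it is exposed in the configuration, as are all other
parameters. The seed is mandatory; identical seed and configuration give
byte-identical output files.

For annotation, the bundle generator writes a random reference sequence
for the causal chromosome and imprints two synthetic genes onto it: *motA*
(minus strand, three exons, 103 codons) whose codon 102 is the serine
codon AGT with its third base at the causal position — so the injected
forward-strand A>T is a T>A transversion on the transcript and annotates
as missense S102R — plus an exon-skipped isoform (the in-frame middle exon
removed) to exercise gene-level aggregation over transcripts; and *nulB*
(plus strand, single exon) placed over a nearby non-causal marker whose
codon is CTN (leucine for any third base), so that marker is synonymous
for every alternate allele and must be removed by the impact filter.
25% of non-causal markers are declared "known sites" to exercise the
known-variants filter.

### What the simulator does not model

Read-level artifacts (mapping error, indel misalignment, duplicates,
base-quality structure), indels and multi-allelic sites, mutation-spectrum
biases of the mutagen, segregation distortion, phenotype misclassification
during sorting, and non-uniform recombination (hot/cold spots,
centromeric suppression). Passing tests therefore demonstrate the
statistical machinery of the mapping method, not robustness to alignment
or calling artifacts of real short-read data.

## Mapping statistics

**Homozygosity score.** Per chromosome and sample, the fraction of
genotyped markers called 1/1. This is the simplest statistic consistent
with a pooled recessive mapping signal: the mutant pool's score is
elevated only on the chromosome carrying the mutation. Chromosome
selection uses the mutant-pool score alone; the sibling track is computed
for plotting and reporting. An `informative_only` variant restricts the
score to markers heterozygous in the sibling pool. Exact ties are broken
by natural chromosome-name order (chr2 before chr13) with a logged
warning.

**Windowed ratio.** Windows of 1 Mb every 0.5 Mb; per window the ratio
`(n_hom + c)/(n_het + c)` of mutant-pool calls with pseudocount `c = 1`,
which keeps fully homozygous windows finite and shrinks small-count
windows toward 1. Windows without genotyped markers are omitted.
Internally windows are 0-based half-open; all user-facing coordinates are
1-based inclusive (BED output is 0-based half-open per the format).

**LOESS.** Tricube-weighted local polynomial regression, implemented
in-repo so its contract is directly testable: at each point a degree-1
polynomial is fitted by weighted least squares to the `⌈span·n⌉` nearest
points with weights `(1 − (|x−x₀|/h)³)³`, `h` the distance to the
farthest neighbour; optional robustness iterations reweight by the
bisquare of scaled residuals. Defaults: span 0.3, degree 1, 0 robustness
iterations. The implementation agrees with an independent per-point
normal-equations oracle to ≤ 1e−10 relative error and with the
statsmodels LOWESS implementation to machine precision on shared
settings.

**Critical region.** The peak is the (first) argmax of the fitted values;
the region is the maximal contiguous run of windows containing the peak
with fitted value ≥ 95% of the peak (`threshold_frac = 0.95`,
configurable and echoed in the output). A peak below
`min_fit_floor = 1.5` is reported as "no linkage detected" — a distinct
pipeline status and CLI exit code (3), not an error. The floor was set
from the null behaviour of the statistic: with ~2 markers per window the
pseudocounted ratio has null expectation at or below 1, so a smoothed
peak above 1.5 requires homozygous calls to clearly dominate. With very
few windows (short chromosomes) the null fluctuation of the smoothed peak
can exceed the floor, so the floor is calibrated for the default
genome-scale design.

**Linked variants.** Records in the region with mutant genotype 1/1 and
sibling genotype 0/0 or 0/1 — the segregation pattern of a recessive
causal variant.

## Consequence annotation

Transcript models (GFF3 via gffutils; sequence via pyfaidx) map a genomic
SNV to a spliced CDS position; on minus-strand transcripts CDS position 1
is the 3′-most genomic CDS base and alleles are complemented. The affected
codon is rebuilt with the alternate base and translated with the standard
genetic code (Biopython); selenocysteine and alternative codes are out of
scope. Types: missense, synonymous, stop_gained, stop_lost, splice_site
(within 2 bp into the intron of an exon/intron boundary — the canonical
donor/acceptor dinucleotides), intron, UTR, intergenic. Impact follows the
four-level scheme used by variant effect predictors: stop_gained /
stop_lost / splice_site HIGH, missense MODERATE, synonymous LOW, intron /
UTR / intergenic MODIFIER. A CDS whose length is not a multiple of 3 is
flagged incomplete and annotated with a warning. Protein positions are
numbered from the initiator methionine of the supplied model, and the
transcript id is always reported alongside — the same variant can carry
different residue numbers on different isoforms, which the report makes
explicit rather than hiding.

Alignment-column conservation is the fraction of non-gap residues
matching the majority residue (ties report the lexicographically smallest
majority; all-gap columns are undefined).

## Candidate cascade

Two per-record predicates — known-site removal (exact match on
chromosome, position and alternate allele; matching on position alone
would discard novel alleles at catalogued positions) and impact filtering
(keep HIGH and MODERATE) — followed by ranking on (impact severity,
conservation, position). The two filters commute; the report carries
every survivor plus a tally of each cascade stage, so no candidate is
hidden by the ranking heuristic.

## Resolution at the default design scale

The default design is deliberately desk-scale: 2 markers/Mb and 40 + 40
pooled embryos at 8–9× yield a smoothed-ratio peak whose location varies
around the causal site with a standard deviation of ≈2 Mb (unbiased; the
pooled allele-frequency curve over 80 meioses per chromosome arm is a
correlated random step function, so the peak scatter is genealogical, not
a sequencing-noise effect that deeper coverage would remove). The
95%-of-peak region is typically 3–5 Mb wide, so it covers the true causal
position in roughly three quarters of replicate studies; the causal
*chromosome* is recovered essentially always. Real studies at full marker
density (one informative SNP every few kb) have far lower peak scatter.
`scripts/acceptance.py` recomputes these rates over 20 replicate seeds;
widening the region (lower `threshold_frac`) trades localisation sharpness
for coverage of the true site.

## Numerical and interface choices

- Genotype tables are read with cyvcf2 (any VCF 4.2 with extra fields is
  accepted; extras ignored) and written in a minimal `GT:GQ:DP:AD`
  dialect by an in-repo serializer, keeping seeded runs byte-identical.
- The QC GQ filter removes the whole record when either sample fails
  (per-sample set-to-missing would silently alter the genotype-pattern
  extraction downstream); each removed record is attributed to exactly
  one rule (first of: non_pass, multi_allelic, missing, low_gq).
  GQ exactly at the threshold is retained (the rule is strictly
  "less than").
- Missing genotypes are dropped by default (configurable); site-level
  caller annotations are honoured only through the FILTER column
  (non-PASS dropped), since recomputing them needs read data.
- Degenerate mapping inputs: a constant fit yields a region spanning all
  windows with the peak at the first maximum; equal-height peaks resolve
  to the leftmost with a warning; chromosomes without markers are
  excluded from selection.
- A neutral cross (no causal site configured) is supported and exercises
  the no-linkage path end to end.
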