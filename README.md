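# homozymap

Homozygosity-based linkage mapping of recessive mutations from pooled F2
genotypes — a mapping-by-sequencing pipeline for forward-genetics screens
(typified by ENU-mutagenized zebrafish), with a built-in cross simulator,
variant consequence annotation and a candidate-reduction cascade.

## The problem and the method

In a forward-genetics screen, a recessive mutation is mapped by incrossing
two heterozygous carriers, sorting the F2 offspring by phenotype into a
homozygous-mutant pool and a phenotypically wild-type sibling pool, and
shallow whole-genome sequencing of both pools. Markers linked to the causal
locus are driven toward homozygosity in the mutant pool, while unlinked
markers segregate 1:2:1 (an expected 25% homozygous-mutant offspring at
every locus, realised only at the causal one by the phenotype sort).

`homozymap` works on a two-sample genotyped variant table (VCF 4.2 with
`GT:GQ:DP:AD`) in five stages:

1. **QC** — hard filters: genotype quality GQ < 5 in either pool,
   multi-allelic sites, missing calls, non-PASS records.
2. **Chromosome selection** — per chromosome and pool, the *homozygosity
   score* `H_c = n(1/1) / n(markers)`; the chromosome maximising the
   mutant-pool score carries the mutation.
3. **Critical region** — sliding windows (1 Mb / 0.5 Mb step) along the
   selected chromosome; per window the pseudocounted ratio
   `(n_hom + 1) / (n_het + 1)` of mutant-pool calls; a tricube local-linear
   LOESS fit (span 0.3, implemented in-repo) smooths the ratio; the region
   is the contiguous run of windows around the fit maximum staying above
   95% of the peak value.
4. **Linked variants** — records inside the region that are `1/1` in the
   mutant pool and `0/0` or `0/1` in the sibling pool.
5. **Candidates** — consequence annotation against transcript models
   (GFF3 + FASTA, full strand handling, standard genetic code), removal of
   sites present in a known-variants catalogue, removal of LOW/MODIFIER
   impact variants, and a ranked report (impact ≻ conservation ≻ position).

The simulator (`homozymap.cross` / `homozymap.bundle`) generates the whole
study from one seed: F2 offspring via Haldane-model meioses
(`r = (1 − e^(−2d))/2`), pooled pseudo-diploid genotype calls from
Poisson-depth binomial reads, a random reference sequence, toy transcript
models around the injected causal missense variant, and a known-sites
catalogue.

## Worked example

```bash
homozymap reproduce --seed 7 -o run7
```

runs the default simulated study (25 chromosomes × 50 Mb, 2 markers/Mb,
40 + 40 pooled embryos at 9×/8× coverage, causal A>T at chr13:29,288,858)
end to end and prints:

```
9 variants entered the cascade; 8 survived the known-site filter; 1 with HIGH/MODERATE impact on 1 gene(s): motA
```

The run log shows the stage outcomes:

```
stage 2: 2254 records retained; removed by rule: {'non_pass': 0, 'multi_allelic': 0, 'missing': 1, 'low_gq': 246}
stage 3: candidate chromosome chr13
stage 3: critical region chr13:28500001-31500000 (3.00 Mb)
stage 4: 9 linked variants in the region
```

and `run7/05_candidates.tsv` contains the recovered causal variant,
annotated on both isoforms of the synthetic causal gene *motA* (the
forward-strand A>T reads T>A on the minus-strand transcript and changes
the serine codon AGT to AGA):

```
Location	Variation	Gene	Transcripts	Consequence	Amino acid	Impact	Mutant GT	Sibling GT	Conservation
chr13:29288858	A to T	motA	motA.1 motA.2	missense	S to R	MODERATE	1/1	0/1	
```

`run7/fig_chromosome_scores.png` (per-chromosome homozygosity scores of
both pools) and `run7/fig_ratio_fit.png` (windowed ratio, LOESS fit,
critical region and peak) visualise the mapping. Each stage is also
available as its own subcommand (`simulate`, `qc`, `map`, `annotate`,
`candidates`, `figures`) for use on real data.

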