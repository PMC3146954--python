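# estsnp

EST-based SNP discovery and population-genetic validation, exercised end to
end on synthetic data with known truth.

## The problem

Developing SNP markers for a non-model organism from expressed sequence
tags (ESTs) is a funnel: clean single-pass cDNA reads, assemble them into
contigs, mine alignment columns for candidate polymorphisms, filter out
everything a genotyping assay cannot use, annotate what survives, and then
*validate* the panel on natural populations — separating neutral markers
from selection candidates before estimating population structure.  The
classic study this package emulates did exactly that for *Daphnia magna*:
stress-exposed EST libraries, a multi-tool SNP pipeline, Sequenom assays,
and six Belgian pond populations scored with Weir–Cockerham F_ST, an
F_ST-versus-heterozygosity outlier scan at a forced mean F_ST, exact
Hardy–Weinberg tests, a Mantel test for isolation by distance, and Bayesian
mixture clustering.

`estsnp` implements that whole workflow as a tested library and CLI.
Because the original raw reads and genotypes are not reproducible at desk
scale, the package ships first-class synthetic generators — EST libraries
with planted biallelic SNPs, Phred-decay errors, polyA tails and adapter
remnants, and island-model genotypes with closed-form control of the true
per-locus differentiation (Balding–Nichols) — so every claim is checked
against planted truth.

## The statistics at the core

* Weir–Cockerham variance components: per-locus θ = a/(a+b+c), multilocus
  θ = Σa/Σ(a+b+c), pairwise θ with permutation P-values.
* Outlier scan: neutral envelope from simulated loci at a simulation F
  calibrated by bisection until mean simulated θ equals the observed
  multilocus θ; 2.5%/97.5% θ quantiles in 20 equal-occupancy
  heterozygosity bins; loci outside their bin's envelope are selection
  candidates, and downstream statistics use the neutral subset.
* Exact conditional Hardy–Weinberg test by full enumeration.
* Mantel test on θ/(1−θ) versus Euclidean distance, exhaustively
  enumerated when the permutation group is small enough.
* Collapsed Bayesian mixture clustering over K = 2–12 (Dirichlet(1)
  weights, Beta(1,1) allele frequencies, stochastic greedy search).
* Four SNP detectors (redundancy, quality, Bayesian posterior, haplotype
  co-segregation) with a ≥3-vote rule and the published filter cascade
  (contiguity, indel and end proximity, flank polymorphism), one marker
  per contig.

See `docs/methods.md` for models, defaults and design choices.

## Worked example

```bash
estsnp simulate --out demo --seed 11 --n-genes 60 --reads-per-gene 8 --snp-rate 0.002
# wrote 494 reads and 186 genotyped individuals to demo

estsnp discover demo/reads.fasta --qual demo/reads.qual --out demo/discover --seed 11
# 494 reads -> 60 contigs -> 24 selected markers (demo/discover)

estsnp validate demo/genotypes.tsv --coords demo/coords.tsv --out demo/validate --seed 11
# global theta 0.1366 over 61 neutral loci; selected K = 6 (demo/validate)
```

`demo/discover/manifest.json` records the funnel — 494 raw reads, 494
trimmed, 60 contigs (59 with at least four members), 1,046 raw variant
columns, 40 candidates with three or more detector votes, 24 selected
markers — and `demo/discover/markers.tsv` carries the annotation, e.g.:

```
contig       position_1based major minor codon_position class aa_change tstv        flank_polymorphisms assay_risk
contig00002  253             C     T     1              S     L>L       transition  0                   low
contig00003  429             C     T     1              NS    A>T       transition  0                   low
contig00004  157             C     G     2              NS    P>R       transversion 1                  low
```

The validate step reads the genotype table, runs the outlier scan first
(here it calls 61 of 62 loci neutral), then computes pairwise F_ST with
permutation significance, the Mantel test, and mixture clustering — which
recovers the six simulated ponds (selected K = 6).

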