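# Methods

`estsnp` re-creates, at desk scale and with fully known truth, the classic
workflow that turns expressed-sequence-tag (EST) libraries into a validated
panel of SNP markers for a non-model organism: read cleaning, overlap
assembly, multi-detector SNP mining with a filter cascade, functional
annotation, and a population-genetic validation battery.  Every stage is
exercised on synthetic data whose generating parameters mirror a published
*Daphnia magna* marker panel (six pond populations at regional scale, a
multilocus F_ST of 0.13, 62 neutral loci, 12 reduced-polymorphism outliers),
so each statistical claim the package makes is checked against a planted
truth rather than against an irreproducible raw dataset.

## Synthetic EST libraries (`synthgen`)

Each gene is a random sequence with one planted open reading frame (120–200
codons drawn from the 61 sense codons) flanked by 40–80 bp UTRs; a short
randomized spacer with stop codons in all three frames sits between the 5'
UTR and the start codon so no upstream ATG can extend the ORF.  Transcripts
carry a 12–25 bp polyA tail.  Polymorphism is planted per base pair at rate
`snp_rate` (default 0.002); each gene has exactly two haplotypes (reference
and alternate), matching the biology of libraries built from two clonal
isolates, and each read draws the alternate haplotype with probability 0.4.
Alternate alleles are transitions with probability 0.5, otherwise a random
transversion.

Reads are windows of the transcript (length ~ Normal(454, 137) clipped to
50–700 bp, reflecting the single-pass Sanger regime this emulates), reverse
complemented with probability 0.5, and 30% carry a 5' SMART-style adapter
remnant.  Phred scores decay linearly from q=40 at the read start to q=15 at
the end (Sanger chromatogram decay); each base is substituted with
probability 10^(−q/10).  The truth table records every gene, ORF, planted
SNP (with per-allele read counts; SNPs never sampled on both alleles are
kept separately as *unrealized*), and full per-read provenance.

What this emulates — and does not: redundancy-based SNP discovery from
moderately deep, error-prone single-pass cDNA reads of two haplotypes.  It
does not emulate chimeric clones, paralog co-assembly, intron contamination,
expression-level-dependent coverage, or more than two haplotypes per gene;
recovery rates on this generator are therefore upper bounds for field data
in those respects, while error handling, strand handling, filter behaviour
and estimator calibration transfer directly.

`discoverable_snps` defines, by pure truth-table arithmetic, which planted
SNPs a redundancy-based pipeline could find at all: coverage ≥ 4 with both
alleles seen ≥ 2 times (after discounting read windows trimming would drop),
at least 70 bp of assembled sequence on both sides (the assay-flank
requirement), no adjacent sibling SNP, and at most 3 sibling SNPs within the
flank window.  Recovery statistics are always quoted against this set.

## Read cleaning (`preprocess`)

Adapters are matched exactly and with one mismatch, at either end, repeated
to a fixed point.  Terminal polyA/polyT runs are stripped when a terminal
segment contains ≥ 10 tail bases and at most one other base (tolerating one
base-calling error inside a tail), again iterated to a fixed point, which
makes trimming idempotent — a property the test suite checks.  Reads with
any 30 bp window containing ≤ 2 distinct bases are discarded as low
complexity (a declared, testable surrogate for chromatogram-era screeners),
and reads shorter than 50 bp after trimming are dropped.  Reads without real
qualities receive a uniform Phred 20, flagged as imputed.

## Assembly (`assemble`)

Reads are clustered by single linkage under "best local overlap ≥ 40
columns at ≥ 93% identity, either strand".  Candidate pairs come from a
shared 16-mer index (low-complexity and over-abundant k-mers masked; all
pairs tested exhaustively below 50 reads), strongest evidence first so the
union-find skips already-connected pairs; overlaps are verified with an
affine-gap local aligner (match +2, mismatch −3, open −5, extend −2), with
identity measured over all alignment columns including gaps.

Each multi-read cluster becomes one contig by star alignment: the longest
member seeds the padded alignment, every other member is aligned to the
evolving consensus, read insertions open new all-gap columns, and members
failing the identity cutoff against the consensus (or overhanging an
interior junction by more than 30 bp) are demoted to singlets.  The
consensus is quality-weighted: per column each base scores the summed Phred
of its supporters, the winner is called with quality = winning minus
runner-up sum (capped at 93), and ties break alphabetically and are flagged.
Coordinates are 0-based half-open throughout; strand of each member is
recorded.  One contig per cluster; no sub-cluster splitting.

## SNP discovery (`snpdiscover`)

Columns with depth ≥ 4 and two observed bases are scanned; a third allele
marks the column multi-allelic and bars it from selection.  Four detectors
vote:

* **COUNT** — minor count ≥ 2 at depth ≥ 4;
* **QUALITY** — COUNT and every minor base call at Phred ≥ 20;
* **BAYES** — posterior P(polymorphic) ≥ 0.5 under a two-allele mixture
  with per-base error e = min(10^(−q/10), 0.75) (a q=0 base is
  uninformative, not anti-informative), the minor-allele frequency profiled
  over {0.1,…,0.5}, the monomorphic likelihood taken as the better
  single-allele explanation, and a prior of 0.003 for polymorphism;
* **HAPLO** — minor-allele reads agree with each other at every other
  *candidate-grade* column they share (co-segregation); with no other such
  column it defers to COUNT.

Candidate-grade means minor count ≥ 2.  Both HAPLO and the flank filters
reason over candidate-grade columns only: singleton mismatches are
overwhelmingly sequencing errors (every read pair carries several under the
default error profile), and counting them as polymorphisms would make
co-segregation fail and the flank filter fire almost everywhere while
carrying no information about real variation.

Filters then flag candidates that are adjacent to another candidate
(CONTIGUOUS), within 10 columns of an alignment gap (NEAR_INDEL), without 70
clean consensus bases on both sides (NEAR_END; 10 bp is the floor for the
raw end-proximity rule, but the flank requirement dominates), or with more
than 3 other candidate columns inside the ±70 bp assay flank (POLY_FLANK) —
the flank-polymorphism threshold re-uses, prospectively, the level at which
assay amplification has been observed to fail.  Among unflagged, biallelic
candidates with ≥ 3 of 4 votes, one marker per contig is selected (most
votes, then highest minor count, then summed minor quality, then leftmost),
avoiding linked markers within one gene.

Recovery is scored in two places by design: *sensitivity* on the accepted
candidate set (votes ≥ 3, unflagged) against discoverable planted SNPs —
the one-marker-per-contig rule intentionally discards second SNPs in a
contig, which is panel design, not detection failure — and *false
discoveries* on the final selected set, which is what a lab would genotype.

## Annotation (`annotate`)

The longest ATG-to-stop ORF across six frames (≥ 30 codons; ties by frame
then leftmost) supplies the reading frame.  Markers inside the ORF get a
codon position, a synonymous/non-synonymous call by translating the
reference and alternate codons (standard nuclear code), and the amino-acid
change; markers outside any ORF are kept as `noncoding` rather than
dropped.  Allele pairs A↔G and C↔T are transitions, the other four
transversions.  The 70 bp flanks are extracted with every other
candidate-grade column written as its IUPAC ambiguity code; a flank with
> 3 other polymorphisms marks the assay `high` risk.  A spectrum table
(codon position × S/NS, six substitution types) summarises a marker set.

## Island-model genotypes and validation statistics (`popgen`)

`generate_island_genotypes` draws, per locus, an ancestral frequency
uniform on [0.1, 0.9] and per-deme frequencies from the Balding–Nichols
parameterisation Beta(mean p, variance F·p·(1−p)), then Binomial(2, ·)
dosages with a 2% missing rate; demes get uniform coordinates in a 40 km
square (the regional scale of the emulated study).  Neutral loci share one
F (default 0.13).  Reduced-polymorphism outliers pin the ancestral
frequency to [0.02, 0.08] (or mirrored) and collapse F to 0.001 —
"frequencies fixed across demes, near 0 or 1" taken literally; elevated
outliers raise F (default 0.45).

* **Per-locus statistics**: allele frequency, observed heterozygosity,
  He = 2p(1−p)·2n/(2n−1), and the exact conditional Hardy–Weinberg test by
  full enumeration of heterozygote counts given allele counts, summing all
  configurations no more likely than the observed one (log-gamma
  arithmetic; ties tolerated at 1e-12 relative).
* **F_ST**: Weir–Cockerham variance components a, b, c, biallelic, unequal
  and missing-aware sample sizes; per-locus θ = a/(a+b+c), multilocus
  θ = Σa/Σ(a+b+c); loci monomorphic over the populations considered drop
  out of the sums.  Pairwise θ carries a permutation P (individuals
  shuffled between the pair; P = (#θ* ≥ θ + 1)/(N + 1), N = 999 default).
* **Outlier scan**: the neutral envelope is simulated (default 10,000
  Balding–Nichols loci, ancestral frequencies uniform [0.02, 0.98], deme
  count and sample sizes matched to the data) at a simulation F calibrated
  by bisection — common random numbers make the simulated mean θ monotone
  in F — until it reproduces the observed multilocus θ within 0.005 (the
  "forced mean F_ST").  Simulated loci are binned into 20 equal-occupancy
  heterozygosity bins (He = 2p̄(1−p̄) from the pooled sample frequency);
  per-bin 2.5%/97.5% θ quantiles form the envelope; observed loci classify
  as low/high outliers or neutral, and zero-He loci are neutral by
  convention with an `unclassifiable` flag.  Power to catch
  reduced-polymorphism loci is intrinsically modest at very low He (the
  neutral envelope widens as conditional θ spread grows), ~55–65% per
  locus at the study conditions; the type-I error sits at the nominal ~5%.
* **Bayesian scan** (optional, off by default): a deliberately simplified
  spike-and-slab logistic decomposition logit(F_ij) = α_i + β_j with
  Beta-binomial deme allele counts, Metropolis updates, P(α=0) = 0.5 a
  priori; the Bayes factor is the posterior inclusion odds and BF ≥ 3
  flags selection.  (A BF of 3 with even prior odds corresponds to a
  posterior of 0.75, not 0.5; the BF threshold is what is implemented.)
  A split-chain inclusion-frequency disagreement above 0.25 marks results
  unreliable.  This is not a reversible-jump sampler and makes no claim to
  full fidelity with one.
* **Mantel**: genetic distance θ/(1−θ), Euclidean geographic distance,
  Pearson r over lower triangles, one-tailed on r ≥ observed.  When the
  group of orderings fits the permutation budget the test enumerates it
  exactly (P = fraction of orderings, identity included); otherwise it
  samples with the +1/(N+1) convention.  θ = 1 anywhere is an error.
* **Mixture clustering**: a K-component collapsed mixture — symmetric
  Dirichlet(1) weights and Beta(1,1) per-locus allele frequencies
  integrated analytically — scored as
  log Γ(K) − log Γ(n+K) + Σ_k[log Γ(n_k+1) + Σ_l log B(c1+1, c0+1)].
  The allocation term matters: without it, maximising over partitions lets
  sampling noise buy extra clusters even in panmictic data.  For each K in
  2–12 a stochastic greedy search (random labels, best-cluster sweeps to a
  fixed point, 20 restarts) keeps the best partition; the selected K
  maximises the score, ties resolving to the smallest K so empty clusters
  never inflate it.  Missing genotypes contribute nothing anywhere
  (pairwise deletion per locus).

## Workflows (`pipeline`, CLI)

`estsnp simulate | discover | validate` chain the stages.  `discover`
writes trimmed FASTA/QUAL, a disposition report, contig FASTA and a
standard ACE alignment file, a candidate table, a marker VCF (CHROM =
contig, POS = 1-based consensus coordinate, REF = major, ALT = minor, INFO
DP/MC/VOTES), an annotated marker table, the spectrum table, and a funnel
manifest (raw → trimmed → contigs → deep contigs → candidates → voted →
selected) with the seed.  `validate` runs the outlier scan first and
computes F_ST, Mantel and clustering on the envelope-neutral subset,
mirroring the practice of validating a marker panel on strictly neutral
loci; degenerate inputs (fewer than two polymorphic loci, identical
coordinates, θ = 1) skip the affected stage with a recorded warning.  All
stage options live in one YAML config; the same config and seed reproduce
byte-identical outputs.

## Problem sizes and numerical choices

The bundled checks run at the emulated study's scale: 200-gene libraries at
~8 reads/gene (≈ 1,600 reads) for discovery recovery; 6 demes × 31
diploids × 62 loci for F_ST recovery (200 seeds) and clustering K recovery
(20 runs); 100-locus panels for envelope calibration (50 neutral
replicates) and power (12 planted outliers per panel).  Envelope
calibration uses 3,000-locus simulations per bisection step and a
10,000-locus envelope.  Detector arithmetic is done in plain probability
space (depths here never exceed a few tens); consensus quality caps at
Phred 93; alignment-identity and permutation conventions are stated above.

## Known limitations

Star alignment is not CAP3: complex indel nests or chimeras would not be
resolved, and only one contig per cluster is emitted.  The six published
discovery tools are represented by four in-repo detector archetypes with a
"≥ 3 of 4" vote standing in for "≥ 3 of 6"; per-tool candidate counts of
the original pipeline are properties of unavailable externals and are not
reproduced.  The ORF caller is longest-ORF, not homology-guided, so UTR
markers in genes whose true frame lacks an in-consensus start codon are
reported noncoding.  The Bayesian outlier scan is a simplified stand-in
model, and the envelope scan's power statement applies to the island model
simulated here, not to arbitrary demographies.
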