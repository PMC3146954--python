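"""Synthetic EST libraries and island-model genotypes with known truth.

Two generators feed the pipeline:

* :func:`generate_est_library` emulates single-pass cDNA reads from a panel of
  expressed genes: each gene carries a full-length open reading frame flanked
  by UTRs, a polyA tail, and a pair of haplotypes differing at planted
  biallelic SNPs.  Reads are windows of the transcript, half of them
  reverse-complemented, optionally carrying a 5' adapter remnant, with
  per-base Phred scores that decay linearly along the read and base errors
  drawn at the implied rate 10^(-q/10).

* :func:`generate_island_genotypes` draws deme allele frequencies from the
  Balding–Nichols model (Beta with mean p and variance F·p·(1-p)) around
  uniform ancestral frequencies, so the true per-locus differentiation F is
  controlled in closed form.  Loci can be planted as outliers: reduced
  polymorphism (frequencies pinned near 0 or 1 in every deme) or elevated
  differentiation.

Every draw comes from one seeded generator, so a repeated call with the same
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import QualityRead, revcomp
from .popgen.genotypes import GenotypeMatrix

__all__ = [
    "SMART_ADAPTER",
    "PhredProfile",
    "PlantedSNP",
    "ReadProvenance",
    "ESTLibraryTruth",
    "generate_est_library",
    "discoverable_snps",
    "OutlierSpec",
    "IslandModelTruth",
    "generate_island_genotypes",
]

#: 5' adapter remnant planted on a fraction of reads (SMART-style oligo).
SMART_ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


def _orf_barrier(rng: np.random.Generator) -> str:
    """Short spacer with a stop codon in all three frames and no ATG.

    Placed between the 5' UTR and the planted start codon so no upstream
    in-frame ATG can extend the ORF.  Stops and spacer bases are drawn
    independently per gene so the motif is not shared across genes (shared
    motifs would let unrelated reads seed spurious overlap candidates).
    """
    while True:
        stops = [_STOPS[rng.integers(len(_STOPS))] for _ in range(3)]
        spacers = [_BASES[rng.integers(len(_BASES))] for _ in range(2)]
        # stop, x, stop, x, stop -> stops land in frames 0, 1 and 2
        seq = stops[0] + spacers[0] + stops[1] + spacers[1] + stops[2]
        if "ATG" not in seq:
            return seq

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class PhredProfile:
    """Linear Phred decay from read start to read end (Sanger-like)."""

    q_start: int = 40
    q_end: int = 15

    def quals(self, length: int) -> list[int]:
        if length == 1:
            return [self.q_start]
        step = (self.q_end - self.q_start) / (length - 1)
        return [int(round(self.q_start + step * i)) for i in range(length)]

    def mean_error_rate(self, length: int = 400) -> float:
        q = np.array(self.quals(length), dtype=float)
        return float(np.mean(10 ** (-q / 10)))


@dataclass
class PlantedSNP:
    gene_id: str
    position: int            # 0-based on the gene reference
    ref: str
    alt: str
    alt_read_count: int = 0  # reads carrying the alt allele over the position
    coverage: int = 0        # reads whose gene window covers the position


@dataclass
class ReadProvenance:
    read_id: str
    gene_id: str
    strand: str              # '+' or '-'
    start: int               # window on the transcript (gene + polyA), 0-based
    end: int
    haplotype: str           # 'ref' or 'alt'
    has_adapter: bool


@dataclass
class ESTLibraryTruth:
    genes: dict[str, str]
    orfs: dict[str, tuple[int, int]]          # ATG..stop span per gene, half-open
    polya_lengths: dict[str, int]
    planted_snps: list[PlantedSNP]            # realized: both alleles among reads
    provenance: list[ReadProvenance]
    unrealized_snps: list[PlantedSNP] = field(default_factory=list)
    adapter: str = SMART_ADAPTER

    def gene_snps(self, gene_id: str) -> list[PlantedSNP]:
        """All planted alleles on a gene, realized in the library or not
        (unrealized ones still sit on every alt-haplotype read)."""
        return [s for s in self.planted_snps + self.unrealized_snps
                if s.gene_id == gene_id]

    def gene_window(self, prov: ReadProvenance) -> tuple[int, int]:
        """Read window clipped to the gene body (excludes the polyA tail)."""
        gene_len = len(self.genes[prov.gene_id])
        return min(prov.start, gene_len), min(prov.end, gene_len)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        snps = pd.DataFrame(
            [(s.gene_id, s.position, s.ref, s.alt, s.alt_read_count, s.coverage,
              realized)
             for snp_list, realized in ((self.planted_snps, True),
                                        (self.unrealized_snps, False))
             for s in snp_list],
            columns=["gene_id", "position", "ref", "alt", "alt_read_count",
                     "coverage", "realized"],
        )
        prov = pd.DataFrame(
            [(p.read_id, p.gene_id, p.strand, p.start, p.end, p.haplotype, p.has_adapter)
             for p in self.provenance],
            columns=["read_id", "gene_id", "strand", "start", "end", "haplotype", "has_adapter"],
        )
        genes = pd.DataFrame(
            [(g, seq, self.orfs[g][0], self.orfs[g][1], self.polya_lengths[g])
             for g, seq in self.genes.items()],
            columns=["gene_id", "sequence", "orf_start", "orf_end", "polya_length"],
        )
        return {"planted_snps": snps, "read_provenance": prov, "genes": genes}


def _random_gene(rng: np.random.Generator, n_codons: int, utr5: int, utr3: int) -> tuple[str, tuple[int, int]]:
    """Random gene with one planted ORF; returns (sequence, ORF span)."""
    head = "".join(rng.choice(list(_BASES), size=utr5)) + _orf_barrier(rng)
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS and codon != "ATG" or not codons:
            # allow internal ATG but keep the first codon the start
            codons.append("ATG" if not codons else codon)
    body = "".join(codons) + _STOPS[rng.integers(len(_STOPS))]
    tail = "".join(rng.choice(list(_BASES), size=utr3))
    start = len(head)
    return head + body + tail, (start, start + len(body))


def generate_est_library(
    n_genes: int = 200,
    reads_per_gene_mean: float = 8.0,
    snp_rate: float = 0.002,
    error_profile: PhredProfile | None = None,
    seed: int = 0,
    *,
    gene_codons: tuple[int, int] = (120, 200),
    utr_length: tuple[int, int] = (40, 80),
    read_length_mean: float = 454.0,
    read_length_sd: float = 137.0,
    read_length_range: tuple[int, int] = (50, 700),
    alt_haplotype_prob: float = 0.4,
    adapter_prob: float = 0.3,
    revcomp_prob: float = 0.5,
    polya_range: tuple[int, int] = (12, 25),
    library_tag: str = "synthetic",
) -> tuple[list[QualityRead], ESTLibraryTruth]:
    """Generate a synthetic EST library with planted SNPs.

    Raises ``ValueError`` for a non-positive gene count or a SNP rate outside
    [0, 0.05].
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= snp_rate <= 0.05:
        raise ValueError("snp_rate must be in [0, 0.05]")
    if reads_per_gene_mean <= 0:
        raise ValueError("reads_per_gene_mean must be positive")
    profile = error_profile or PhredProfile()
    rng = np.random.default_rng(seed)

    genes: dict[str, str] = {}
    orfs: dict[str, tuple[int, int]] = {}
    polya: dict[str, int] = {}
    snps_by_gene: dict[str, list[PlantedSNP]] = {}
    for gi in range(n_genes):
        gene_id = f"g{gi + 1:04d}"
        n_codons = int(rng.integers(gene_codons[0], gene_codons[1] + 1))
        utr5 = int(rng.integers(utr_length[0], utr_length[1] + 1))
        utr3 = int(rng.integers(utr_length[0], utr_length[1] + 1))
        seq, orf = _random_gene(rng, n_codons, utr5, utr3)
        genes[gene_id] = seq
        orfs[gene_id] = orf
        polya[gene_id] = int(rng.integers(polya_range[0], polya_range[1] + 1))
        gene_snps = []
        if snp_rate > 0:
            hits = np.flatnonzero(rng.random(len(seq)) < snp_rate)
            for pos in hits:
                ref = seq[pos]
                if rng.random() < 0.5:
                    alt = _TRANSITION[ref]
                else:
                    alt = rng.choice([b for b in _BASES if b != ref and b != _TRANSITION[ref]])
                gene_snps.append(PlantedSNP(gene_id, int(pos), ref, str(alt)))
        snps_by_gene[gene_id] = gene_snps

    reads: list[QualityRead] = []
    provenance: list[ReadProvenance] = []
    counter = 0
    for gene_id, seq in genes.items():
        gene_snps = snps_by_gene[gene_id]
        alt_seq = list(seq)
        for s in gene_snps:
            alt_seq[s.position] = s.alt
        alt_seq = "".join(alt_seq)
        transcript_ref = seq + "A" * polya[gene_id]
        transcript_alt = alt_seq + "A" * polya[gene_id]
        n_reads = max(1, int(rng.poisson(reads_per_gene_mean)))
        for _ in range(n_reads):
            counter += 1
            read_id = f"r{counter:06d}"
            length = int(round(rng.normal(read_length_mean, read_length_sd)))
            length = int(np.clip(length, read_length_range[0],
                                 min(read_length_range[1], len(transcript_ref))))
            start = int(rng.integers(0, len(transcript_ref) - length + 1))
            end = start + length
            haplotype = "alt" if rng.random() < alt_haplotype_prob else "ref"
            template = transcript_alt if haplotype == "alt" else transcript_ref
            bases = template[start:end]
            strand = "-" if rng.random() < revcomp_prob else "+"
            if strand == "-":
                bases = revcomp(bases)
            has_adapter = bool(rng.random() < adapter_prob)
            if has_adapter:
                bases = SMART_ADAPTER + bases
            quals = profile.quals(len(bases))
            err_p = 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)
            flips = np.flatnonzero(rng.random(len(bases)) < err_p)
            if flips.size:
                chars = list(bases)
                for i in flips:
                    chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
                bases = "".join(chars)
            reads.append(QualityRead(read_id, bases, quals, library_tag))
            provenance.append(ReadProvenance(read_id, gene_id, strand, start, end,
                                             haplotype, has_adapter))

    truth = ESTLibraryTruth(genes, orfs, polya, [], provenance)
    # per-SNP coverage and alt counts over reads whose gene window spans the
    # site; SNPs never seen on both alleles are not library polymorphisms but
    # alt-haplotype reads still carry them, so they are kept as unrealized
    planted: list[PlantedSNP] = []
    unrealized: list[PlantedSNP] = []
    for gene_id, gene_snps in snps_by_gene.items():
        provs = [p for p in provenance if p.gene_id == gene_id]
        for s in gene_snps:
            cov = alt = 0
            for p in provs:
                lo, hi = truth.gene_window(p)
                if lo <= s.position < hi:
                    cov += 1
                    alt += p.haplotype == "alt"
            s.coverage, s.alt_read_count = cov, alt
            (planted if min(alt, cov - alt) >= 1 else unrealized).append(s)
    truth.planted_snps = planted
    truth.unrealized_snps = unrealized
    return reads, truth


def discoverable_snps(
    truth: ESTLibraryTruth,
    *,
    min_depth: int = 4,
    min_minor_count: int = 2,
    min_read_length: int = 50,
    min_overlap: int = 40,
    end_margin: int = 10,
    flank_window: int = 70,
    max_flank_polymorphisms: int = 3,
) -> list[PlantedSNP]:
    """Planted SNPs a redundancy-based scan of the truth table deems findable.

    A SNP is discoverable when: enough reads (after discounting windows that
    trimming would shrink below ``min_read_length``) cover it on both alleles;
    it sits at least ``max(end_margin, flank_window)`` inside the extent of
    its read-overlap component (assay flanks must fit); no sibling SNP is
    adjacent to it; and at most ``max_flank_polymorphisms`` sibling SNPs fall
    within the flank window.  Pure truth-table arithmetic — no pipeline code.
    """
    by_gene: dict[str, list[ReadProvenance]] = {}
    for p in truth.provenance:
        lo, hi = truth.gene_window(p)
        if hi - lo >= min_read_length:
            by_gene.setdefault(p.gene_id, []).append(p)
    margin = max(end_margin, flank_window)
    out: list[PlantedSNP] = []
    snps_by_gene: dict[str, list[PlantedSNP]] = {}
    for s in truth.planted_snps:
        snps_by_gene.setdefault(s.gene_id, []).append(s)
    for s in truth.planted_snps:
        provs = by_gene.get(s.gene_id, [])
        covering = [p for p in provs
                    if truth.gene_window(p)[0] <= s.position < truth.gene_window(p)[1]]
        depth = len(covering)
        alt = sum(p.haplotype == "alt" for p in covering)
        if depth < min_depth or min(alt, depth - alt) < min_minor_count:
            continue
        # single-linkage component of read windows overlapping by >= min_overlap
        intervals = [truth.gene_window(p) for p in provs]
        seed_iv = truth.gene_window(covering[0])
        component = [seed_iv]
        rest = [iv for iv in intervals if iv != seed_iv]
        grew = True
        while grew:
            grew = False
            for iv in list(rest):
                if any(min(iv[1], c[1]) - max(iv[0], c[0]) >= min_overlap for c in component):
                    component.append(iv)
                    rest.remove(iv)
                    grew = True
        lo = min(iv[0] for iv in component)
        hi = max(iv[1] for iv in component)
        if s.position - lo < margin or (hi - 1) - s.position < margin:
            continue
        siblings = [o for o in snps_by_gene[s.gene_id] if o.position != s.position]
        if any(abs(o.position - s.position) <= 1 for o in siblings):
            continue
        n_flank = sum(abs(o.position - s.position) <= flank_window for o in siblings)
        if n_flank > max_flank_polymorphisms:
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Island-model genotypes
# ---------------------------------------------------------------------------


@dataclass
class OutlierSpec:
    """How to perturb a fraction of loci away from the shared neutral F.

    kind 'reduced_polymorphism': ancestral frequency pinned near 0 or 1 and
    differentiation collapsed (frequencies nearly identical across demes).
    kind 'elevated_differentiation': F raised to ``f_true``.
    """

    kind: str
    fraction: float
    f_true: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("reduced_polymorphism", "elevated_differentiation"):
            raise ValueError(f"unknown outlier kind {self.kind!r}")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")


@dataclass
class IslandModelTruth:
    n_demes: int
    ancestral_freq: np.ndarray      # per locus
    f_true: np.ndarray              # per locus
    selection_flag: list[str]       # neutral | reduced_polymorphism | elevated_differentiation
    coords: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": [f"L{i + 1:04d}" for i in range(len(self.f_true))],
            "ancestral_freq": self.ancestral_freq,
            "f_true": self.f_true,
            "selection_flag": self.selection_flag,
        })


def balding_nichols_freqs(p: np.ndarray, f: np.ndarray, n_demes: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-deme allele frequencies: Beta(mean p, variance f*p*(1-p)).

    Returns an (n_demes, n_loci) array.  f == 0 entries collapse to p.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    f = np.broadcast_to(np.asarray(f, dtype=float), p.shape)
    lam = (1.0 - f) / np.maximum(f, 1e-12)
    freqs = rng.beta(np.maximum(p * lam, 1e-9), np.maximum((1 - p) * lam, 1e-9),
                     size=(n_demes, p.size))
    return np.where(f <= 0, p, freqs)


def generate_island_genotypes(
    n_demes: int = 6,
    n_per_deme: int = 31,
    n_loci: int = 62,
    f_neutral: float = 0.13,
    outlier_spec: list[OutlierSpec] | None = None,
    seed: int = 0,
    *,
    missing_rate: float = 0.02,
    ancestral_range: tuple[float, float] = (0.1, 0.9),
    reduced_f: float = 0.001,
    box_km: float = 40.0,
) -> tuple[GenotypeMatrix, IslandModelTruth]:
    """Island-model genotypes with known per-locus differentiation.

    Neutral loci share ``f_neutral``; planted outliers follow their
    :class:`OutlierSpec`.  Genotypes are Binomial(2, deme frequency) dosages
    with a small missing-call rate; demes get uniform coordinates in a square
    of side ``box_km``.
    """
    if min(n_demes, n_per_deme, n_loci) < 1:
        raise ValueError("n_demes, n_per_deme and n_loci must all be >= 1")
    if not 0 < f_neutral < 1:
        raise ValueError("f_neutral must be in (0, 1)")
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(*ancestral_range, size=n_loci)
    f_true = np.full(n_loci, f_neutral)
    flags = ["neutral"] * n_loci
    available = list(range(n_loci))
    for spec in outlier_spec or []:
        count = int(round(spec.fraction * n_loci))
        chosen = rng.choice(available, size=min(count, len(available)), replace=False)
        for i in sorted(int(c) for c in chosen):
            available.remove(i)
            flags[i] = spec.kind
            if spec.kind == "reduced_polymorphism":
                extreme = rng.uniform(0.02, 0.08)
                p_anc[i] = extreme if rng.random() < 0.5 else 1.0 - extreme
                f_true[i] = reduced_f
            else:
                f_true[i] = spec.f_true if spec.f_true is not None else 0.45

    deme_freqs = balding_nichols_freqs(p_anc, f_true, n_demes, rng)  # (demes, loci)
    dosages = np.empty((n_demes * n_per_deme, n_loci), dtype=float)
    pops: list[str] = []
    individuals: list[str] = []
    for d in range(n_demes):
        pop = f"pond{d + 1}"
        block = rng.binomial(2, deme_freqs[d], size=(n_per_deme, n_loci))
        dosages[d * n_per_deme : (d + 1) * n_per_deme] = block
        pops.extend([pop] * n_per_deme)
        individuals.extend(f"{pop}_i{i + 1:03d}" for i in range(n_per_deme))
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan

    coords = pd.DataFrame({
        "population": [f"pond{d + 1}" for d in range(n_demes)],
        "x_km": rng.uniform(0, box_km, size=n_demes),
        "y_km": rng.uniform(0, box_km, size=n_demes),
    })
    loci = [f"L{i + 1:04d}" for i in range(n_loci)]
    g = GenotypeMatrix(dosages, individuals, pops, loci, coords)
    truth = IslandModelTruth(n_demes, p_anc, f_true, flags, coords)
    return g, truth
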