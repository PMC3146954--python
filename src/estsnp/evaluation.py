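"""Scoring pipeline output against the synthetic truth tables.

Maps each contig consensus back onto its source gene (either orientation),
then compares candidate/selected SNP columns with the planted SNP positions.
Used by the recovery tests and the acceptance report; everything here reads
the truth tables, never the pipeline's internals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .assemble import Contig
from .preprocess import revcomp
from .snpdiscover import SNPCandidate
from .synthgen import ESTLibraryTruth, discoverable_snps

__all__ = ["RecoveryScore", "score_discovery", "map_contig_to_gene"]


@dataclass
class RecoveryScore:
    n_discoverable: int
    n_recovered: int            # discoverable SNPs present among accepted candidates
    n_selected: int
    n_false_selected: int       # selected markers at positions with no planted SNP
    n_unmapped_contigs: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_discoverable if self.n_discoverable else 1.0

    @property
    def false_discovery_rate(self) -> float:
        return self.n_false_selected / self.n_selected if self.n_selected else 0.0


def map_contig_to_gene(contig: Contig, truth: ESTLibraryTruth,
                       probe_len: int = 30) -> tuple[str, int, int] | None:
    """(gene_id, offset, direction) mapping consensus columns to gene
    positions: gene_pos = offset + direction * column.

    The gene is the majority provenance of the contig members; the offset is
    anchored by exact probe search in either orientation, probing several
    consensus windows so isolated consensus errors cannot block the match.
    """
    prov = {p.read_id: p.gene_id for p in truth.provenance}
    genes = Counter(prov[r.read_id] for r in contig.rows if r.read_id in prov)
    if not genes:
        return None
    gene_id = genes.most_common(1)[0][0]
    gene_seq = truth.genes[gene_id]
    cons = contig.consensus
    for start in range(0, max(1, len(cons) - probe_len), 37):
        probe = cons[start : start + probe_len]
        if len(probe) < probe_len:
            break
        idx = gene_seq.find(probe)
        if idx >= 0:
            return gene_id, idx - start, +1
        idx = gene_seq.find(revcomp(probe))
        if idx >= 0:
            # column start+k maps to gene position idx+probe_len-1-k
            return gene_id, idx + probe_len - 1 + start, -1
    return None


def score_discovery(contigs: list[Contig], candidates: list[SNPCandidate],
                    selected: list[SNPCandidate], truth: ESTLibraryTruth,
                    min_votes: int = 3, position_slack: int = 2) -> RecoveryScore:
    """Score accepted candidates and selected markers against planted SNPs.

    Sensitivity is measured on accepted candidates (enough votes, unflagged,
    biallelic) against the discoverable planted set; the false-discovery
    count covers the final one-per-contig selection.  ``position_slack``
    tolerates small coordinate shifts from alignment padding.
    """
    mapping = {c.contig_id: map_contig_to_gene(c, truth) for c in contigs}
    n_unmapped = sum(1 for v in mapping.values() if v is None)

    def gene_position(cand: SNPCandidate) -> tuple[str, int] | None:
        m = mapping.get(cand.contig_id)
        if m is None:
            return None
        gene_id, offset, direction = m
        return gene_id, offset + direction * cand.column

    truth_positions = {(s.gene_id, s.position) for s in truth.planted_snps}
    disc = {(s.gene_id, s.position) for s in discoverable_snps(truth)}

    accepted = [c for c in candidates
                if len(c.votes) >= min_votes and not c.filter_flags
                and not c.multiallelic]
    accepted_positions = {p for p in (gene_position(c) for c in accepted)
                          if p is not None}

    def near(target: tuple[str, int], pool: set[tuple[str, int]]) -> bool:
        gene, pos = target
        return any(g == gene and abs(p - pos) <= position_slack for g, p in pool)

    n_recovered = sum(1 for t in disc if near(t, accepted_positions))
    n_false = 0
    for cand in selected:
        p = gene_position(cand)
        if p is None or not near(p, truth_positions):
            n_false += 1
    return RecoveryScore(
        n_discoverable=len(disc),
        n_recovered=n_recovered,
        n_selected=len(selected),
        n_false_selected=n_false,
        n_unmapped_contigs=n_unmapped,
    )
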