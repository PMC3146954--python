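"""Candidate SNP detection in contig columns, detector voting, filtering,
and one-marker-per-contig selection.

Four detectors, each an archetype of the published EST-SNP callers, examine
every variant column of a contig:

COUNT    redundancy: the minor allele is seen at least ``min_minor_count``
         times in a column of depth at least ``min_depth``.
QUALITY  as COUNT, but additionally every minor-allele base call must reach
         the quality floor.
BAYES    posterior probability that the column is polymorphic, from per-base
         Phred error rates, a grid over the minor-allele frequency and a
         small prior for polymorphism.
HAPLO    haplotype consistency: reads carrying the minor allele must agree
         with one another at every other candidate column they share, i.e.
         the site must co-segregate rather than scatter like paralog noise
         or random error.

A column is accepted when at least ``min_votes`` detectors agree and no
exclusion filter fires (contiguous candidates, proximity to an alignment gap
or the contig ends, an over-polymorphic assay flank).  At most one accepted
candidate per contig is promoted to a marker.

Detectors and filters deliberately reason over *candidate-grade* columns
(minor count at or above the redundancy floor): singleton mismatches are
overwhelmingly base-calling errors, and treating them as polymorphisms would
poison both the co-segregation test and the flank-polymorphism count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assemble import Contig, column_profile

__all__ = ["SNPCandidate", "DiscoveryConfig", "scan_columns", "run_detectors",
           "apply_filters", "select_markers", "discover_snps"]

_ALPHABET = "ACGT"


@dataclass
class SNPCandidate:
    contig_id: str
    column: int                      # 0-based consensus coordinate
    major_allele: str
    minor_allele: str
    depth: int
    minor_count: int
    major_count: int
    mean_major_qual: float
    mean_minor_qual: float
    multiallelic: bool = False
    votes: set[str] = field(default_factory=set)
    filter_flags: set[str] = field(default_factory=set)
    selected: bool = False
    bayes_posterior: float | None = None

    @property
    def alleles(self) -> tuple[str, str]:
        return self.major_allele, self.minor_allele


@dataclass
class DiscoveryConfig:
    min_depth: int = 4
    min_minor_count: int = 2
    min_votes: int = 3
    quality_detector_min_q: int = 20
    bayes_prior_poly: float = 0.003
    bayes_posterior_min: float = 0.5
    end_margin: int = 10
    indel_margin: int = 10
    flank_window: int = 70
    max_flank_polymorphisms: int = 3

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_minor_count", "min_votes", "end_margin",
                     "indel_margin", "flank_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.min_votes > 4:
            raise ValueError("min_votes cannot exceed the four detectors")


def scan_columns(contig: Contig, cfg: DiscoveryConfig | None = None) -> list[SNPCandidate]:
    """Raw variant columns: depth >= min_depth and at least two distinct
    bases observed.  Columns with a third allele are emitted but marked
    multi-allelic (excluded from marker selection downstream)."""
    cfg = cfg or DiscoveryConfig()
    scores, counts, depth, _ = column_profile(contig)
    out: list[SNPCandidate] = []
    for col in np.flatnonzero((depth >= cfg.min_depth) & ((counts > 0).sum(axis=1) >= 2)):
        col = int(col)
        order = np.lexsort((-scores[col], -counts[col]))  # count desc, then quality desc
        maj, minr = int(order[0]), int(order[1])
        out.append(SNPCandidate(
            contig_id=contig.contig_id,
            column=col,
            major_allele=_ALPHABET[maj],
            minor_allele=_ALPHABET[minr],
            depth=int(depth[col]),
            minor_count=int(counts[col, minr]),
            major_count=int(counts[col, maj]),
            mean_major_qual=float(scores[col, maj] / max(counts[col, maj], 1)),
            mean_minor_qual=float(scores[col, minr] / max(counts[col, minr], 1)),
            multiallelic=bool((counts[col] > 0).sum() > 2),
        ))
    return out


def _candidate_grade(candidates: list[SNPCandidate], cfg: DiscoveryConfig) -> list[SNPCandidate]:
    return [c for c in candidates if c.minor_count >= cfg.min_minor_count]


def _bayes_posterior(bases: list[str], quals: list[int], major: str, minor: str,
                     cfg: DiscoveryConfig) -> float:
    """P(column polymorphic) under a two-allele mixture with Phred errors.

    Error probability per base is min(10^(-q/10), 0.75), so a q=0 base is
    uninformative rather than anti-informative.  The monomorphic likelihood
    is the better of the two single-allele explanations; the polymorphic
    likelihood profiles the minor-allele frequency over {0.1..0.5}.
    """
    e = np.minimum(10 ** (-np.asarray(quals, dtype=float) / 10), 0.75)
    obs = np.asarray(bases)
    lik_major = np.where(obs == major, 1 - e, e / 3)
    lik_minor = np.where(obs == minor, 1 - e, e / 3)
    l_mono = max(float(np.prod(lik_major)), float(np.prod(lik_minor)))
    l_poly = max(
        float(np.prod(f * lik_minor + (1 - f) * lik_major))
        for f in (0.1, 0.2, 0.3, 0.4, 0.5)
    )
    prior = cfg.bayes_prior_poly
    num = prior * l_poly
    den = num + (1 - prior) * l_mono
    return num / den if den > 0 else 0.0


def run_detectors(contig: Contig, candidate: SNPCandidate,
                  all_candidates: list[SNPCandidate],
                  cfg: DiscoveryConfig | None = None) -> set[str]:
    """Vote the four detectors on one raw variant column."""
    cfg = cfg or DiscoveryConfig()
    votes: set[str] = set()
    count_ok = (candidate.minor_count >= cfg.min_minor_count
                and candidate.depth >= cfg.min_depth)
    if count_ok:
        votes.add("COUNT")

    entries = contig.column(candidate.column)
    minor_rows = [(i, q) for i, b, q in entries if b == candidate.minor_allele]
    if count_ok and all((q or 0) >= cfg.quality_detector_min_q for _, q in minor_rows):
        votes.add("QUALITY")

    bases = [b for _, b, _ in entries]
    quals = [q or 0 for _, _, q in entries]
    posterior = _bayes_posterior(bases, quals, candidate.major_allele,
                                 candidate.minor_allele, cfg)
    candidate.bayes_posterior = posterior
    if posterior >= cfg.bayes_posterior_min:
        votes.add("BAYES")

    other_cols = [c.column for c in _candidate_grade(all_candidates, cfg)
                  if c.column != candidate.column]
    if not other_cols:
        if count_ok:
            votes.add("HAPLO")      # nothing to co-segregate with: defer to COUNT
    else:
        consistent = True
        minor_row_idx = [i for i, _ in minor_rows]
        for col in other_cols:
            seen = {contig.rows[i].base_at(col) for i in minor_row_idx}
            seen.discard(None)
            seen.discard("-")
            if len(seen) > 1:
                consistent = False
                break
        if consistent and count_ok:
            votes.add("HAPLO")
    candidate.votes = votes
    return votes


def apply_filters(contig: Contig, candidates: list[SNPCandidate],
                  cfg: DiscoveryConfig | None = None) -> list[SNPCandidate]:
    """Set exclusion flags on every candidate.

    CONTIGUOUS — an adjacent (distance 1) candidate-grade pair, both flagged.
    NEAR_INDEL — an alignment gap column within ``indel_margin``.
    NEAR_END   — too close to the consensus ends for a clean assay flank.
    POLY_FLANK — more than ``max_flank_polymorphisms`` other candidate-grade
                 columns inside the flank window.
    """
    cfg = cfg or DiscoveryConfig()
    length = len(contig.consensus)
    gap_cols = np.array(sorted(contig.gap_columns()), dtype=int)
    grade_cols = np.array([c.column for c in _candidate_grade(candidates, cfg)], dtype=int)
    for cand in candidates:
        col = cand.column
        if (grade_cols.size and cand.minor_count >= cfg.min_minor_count
                and (np.abs(grade_cols - col) == 1).any()):
            cand.filter_flags.add("CONTIGUOUS")
        if gap_cols.size and (np.abs(gap_cols - col) <= cfg.indel_margin).any():
            cand.filter_flags.add("NEAR_INDEL")
        margin = max(cfg.end_margin, cfg.flank_window)
        if col < margin or col > length - margin - 1:
            cand.filter_flags.add("NEAR_END")
        n_flank = int(((np.abs(grade_cols - col) <= cfg.flank_window)
                       & (grade_cols != col)).sum()) if grade_cols.size else 0
        if n_flank > cfg.max_flank_polymorphisms:
            cand.filter_flags.add("POLY_FLANK")
    return candidates


def select_markers(candidates: list[SNPCandidate],
                   cfg: DiscoveryConfig | None = None) -> list[SNPCandidate]:
    """At most one marker per contig: unflagged, biallelic, >= min_votes;
    preferring more votes, then higher minor count, then higher summed
    minor-allele quality, then the leftmost column."""
    cfg = cfg or DiscoveryConfig()
    by_contig: dict[str, list[SNPCandidate]] = {}
    for cand in candidates:
        by_contig.setdefault(cand.contig_id, []).append(cand)
    selected: list[SNPCandidate] = []
    for contig_id in sorted(by_contig):
        eligible = [c for c in by_contig[contig_id]
                    if len(c.votes) >= cfg.min_votes and not c.filter_flags
                    and not c.multiallelic]
        if not eligible:
            continue
        best = min(eligible, key=lambda c: (
            -len(c.votes), -c.minor_count,
            -c.mean_minor_qual * c.minor_count, c.column))
        best.selected = True
        selected.append(best)
    return selected


def discover_snps(contigs: list[Contig], cfg: DiscoveryConfig | None = None
                  ) -> tuple[list[SNPCandidate], list[SNPCandidate]]:
    """Full per-contig discovery: scan, vote, filter, select.

    Returns (all candidates across contigs, selected markers).
    """
    cfg = cfg or DiscoveryConfig()
    all_candidates: list[SNPCandidate] = []
    selected: list[SNPCandidate] = []
    for contig in contigs:
        candidates = scan_columns(contig, cfg)
        for cand in candidates:
            run_detectors(contig, cand, candidates, cfg)
        apply_filters(contig, candidates, cfg)
        selected.extend(select_markers(candidates, cfg))
        all_candidates.extend(candidates)
    return all_candidates, selected
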