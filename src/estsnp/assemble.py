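"""Overlap clustering and star alignment of trimmed EST reads.

Reads are grouped by single linkage under the predicate "best local overlap of
at least ``min_overlap_length`` columns at ``min_overlap_identity`` percent
identity, on either strand".  Each cluster of two or more reads becomes one
contig: the longest member seeds a star alignment and every other member is
aligned to the evolving quality-weighted consensus; members that no longer
reach the identity cutoff against the consensus are demoted to singlets.

Candidate read pairs are pre-screened with a shared k-mer index so that only
plausible overlaps reach the (exact, affine-gap) local aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .preprocess import QualityRead, revcomp

__all__ = ["AssemblyConfig", "AlignedRead", "Contig", "cluster_reads",
           "align_cluster", "call_consensus", "assemble"]


@dataclass
class AssemblyConfig:
    min_overlap_identity: float = 93.0   # percent
    min_overlap_length: int = 40         # bp
    max_unaligned_overhang: int = 30     # bp of interior overhang before demotion
    kmer_size: int = 16
    min_shared_kmers: int = 2
    max_kmer_occupancy: int = 30         # k-mers seen in more reads are masked
    exhaustive_below: int = 50           # skip the k-mer screen for tiny inputs

    def __post_init__(self) -> None:
        if not 50 < self.min_overlap_identity <= 100:
            raise ValueError("min_overlap_identity must be in (50, 100]")
        if self.min_overlap_length < 20:
            raise ValueError("min_overlap_length must be >= 20")


@dataclass
class AlignedRead:
    """One contig member as placed in the padded alignment."""

    read_id: str
    strand: str                      # '+' as given, '-' stored reverse-complemented
    start_col: int
    aligned_seq: str                 # over {A,C,G,T,N,-}; '-' marks internal gaps
    aligned_quals: list[int | None]  # None at gap columns

    @property
    def end_col(self) -> int:
        return self.start_col + len(self.aligned_seq)

    def base_at(self, col: int) -> str | None:
        if not self.start_col <= col < self.end_col:
            return None
        return self.aligned_seq[col - self.start_col]

    def qual_at(self, col: int) -> int | None:
        if not self.start_col <= col < self.end_col:
            return None
        return self.aligned_quals[col - self.start_col]


@dataclass
class Contig:
    contig_id: str
    rows: list[AlignedRead]
    consensus: str = ""
    consensus_quals: list[int] = field(default_factory=list)
    tie_columns: set[int] = field(default_factory=set)

    @property
    def n_columns(self) -> int:
        return max((r.end_col for r in self.rows), default=0)

    def column(self, col: int) -> list[tuple[int, str, int | None]]:
        """(row index, base, quality) for every member covering ``col`` with a
        non-gap character."""
        out = []
        for i, row in enumerate(self.rows):
            base = row.base_at(col)
            if base is not None and base != "-":
                out.append((i, base, row.qual_at(col)))
        return out

    def depth(self, col: int) -> int:
        return len(self.column(col))

    def depths(self) -> list[int]:
        return [self.depth(c) for c in range(self.n_columns)]

    def gap_columns(self) -> set[int]:
        cols: set[int] = set()
        for row in self.rows:
            for off, ch in enumerate(row.aligned_seq):
                if ch == "-":
                    cols.add(row.start_col + off)
        return cols

    def padded_consensus(self) -> str:
        return self.consensus

    def padded_consensus_quals(self) -> list[int]:
        return list(self.consensus_quals)


def _aligner(cfg: AssemblyConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """(matches, alignment columns incl. internal gaps, aligned block pairs)."""
    blocks_t, blocks_q = alignment.aligned
    target, query = alignment.target, alignment.query
    matches = 0
    columns = 0
    pairs = []
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)
        for i in range(t1 - t0):
            matches += target[t0 + i] == query[q0 + i]
        columns += t1 - t0
        pairs.append(((int(t0), int(t1)), (int(q0), int(q1))))
        prev_t, prev_q = t1, q1
    return matches, columns, pairs


def _best_overlap(a: str, b: str, cfg: AssemblyConfig, aligner=None):
    """Best local overlap of ``b`` (either strand) against ``a``.

    Returns (identity_percent, columns, orientation, alignment) or None when
    nothing aligns.
    """
    aligner = aligner or _aligner(cfg)
    best = None
    for orientation, seq in (("+", b), ("-", revcomp(b))):
        alignments = aligner.align(a, seq)
        try:
            aln = alignments[0]
        except (IndexError, ValueError):
            continue
        matches, columns, _ = _alignment_stats(aln)
        if columns == 0:
            continue
        identity = 100.0 * matches / columns
        key = (aln.score, identity)
        if best is None or key > best[0]:
            best = (key, identity, columns, orientation, aln)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def _overlap_orientation(a: QualityRead, b: QualityRead, cfg: AssemblyConfig,
                         aligner, try_first: str = "+") -> bool:
    """Whether ``b`` overlaps ``a`` on either strand, testing the hinted
    orientation first to halve aligner calls on true positives."""
    order = (try_first, "-" if try_first == "+" else "+")
    for orientation in order:
        seq = b.bases if orientation == "+" else revcomp(b.bases)
        alignments = aligner.align(a.bases, seq)
        try:
            aln = alignments[0]
        except (IndexError, ValueError):
            continue
        matches, columns, _ = _alignment_stats(aln)
        if (columns >= cfg.min_overlap_length
                and 100.0 * matches / columns >= cfg.min_overlap_identity):
            return True
    return False


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if len(set(kmer)) > 2:  # skip low-complexity seeds (polyA etc.)
            yield kmer


def _candidate_pairs(reads: list[QualityRead], cfg: AssemblyConfig
                     ) -> list[tuple[int, int, str]]:
    """Read pairs worth aligning, strongest shared-k-mer evidence first.

    Returns (i, j, orientation hint).  Over-abundant k-mers (shared motifs,
    repeats) are masked from the index so they cannot pair unrelated reads.
    For small inputs every pair is emitted (both-strand hint resolution still
    applies)."""
    if len(reads) <= cfg.exhaustive_below:
        return [(i, j, "+") for i in range(len(reads))
                for j in range(i + 1, len(reads))]
    index: dict[str, list[int]] = {}
    for idx, read in enumerate(reads):
        for kmer in set(_kmers(read.bases, cfg.kmer_size)):
            index.setdefault(kmer, []).append(idx)
    index = {k: v for k, v in index.items() if len(v) <= cfg.max_kmer_occupancy}
    fwd: dict[tuple[int, int], int] = {}
    rev: dict[tuple[int, int], int] = {}
    for idx, read in enumerate(reads):
        for counts, probe in ((fwd, read.bases), (rev, revcomp(read.bases))):
            for kmer in set(_kmers(probe, cfg.kmer_size)):
                for other in index.get(kmer, ()):
                    if other > idx:
                        counts[(idx, other)] = counts.get((idx, other), 0) + 1
    merged: dict[tuple[int, int], tuple[int, str]] = {}
    for pair in set(fwd) | set(rev):
        f, r = fwd.get(pair, 0), rev.get(pair, 0)
        merged[pair] = (max(f, r), "+" if f >= r else "-")
    keep = [(count, pair, hint) for pair, (count, hint) in merged.items()
            if count >= cfg.min_shared_kmers]
    keep.sort(key=lambda t: (-t[0], t[1]))
    return [(i, j, hint) for _, (i, j), hint in keep]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_reads(reads: list[QualityRead], cfg: AssemblyConfig | None = None
                  ) -> tuple[list[list[QualityRead]], list[QualityRead]]:
    """Single-linkage clusters and singlets.

    Deterministic: reads are processed sorted by length (desc) then id, and
    cluster order follows that of their first member.
    """
    cfg = cfg or AssemblyConfig()
    ordered = sorted(reads, key=lambda r: (-len(r.bases), r.read_id))
    aligner = _aligner(cfg)
    uf = _UnionFind(len(ordered))
    for i, j, hint in _candidate_pairs(ordered, cfg):
        if uf.find(i) == uf.find(j):
            continue
        if _overlap_orientation(ordered[i], ordered[j], cfg, aligner, hint):
            uf.union(i, j)
    groups: dict[int, list[QualityRead]] = {}
    for idx, read in enumerate(ordered):
        groups.setdefault(uf.find(idx), []).append(read)
    clusters = [g for _, g in sorted(groups.items()) if len(g) > 1]
    singlets = [g[0] for _, g in sorted(groups.items()) if len(g) == 1]
    return clusters, singlets


def _insert_columns(rows: list[AlignedRead], col: int, count: int) -> None:
    """Open ``count`` new all-gap columns immediately before column ``col``."""
    for row in rows:
        if col <= row.start_col:
            row.start_col += count
        elif col < row.end_col:
            off = col - row.start_col
            row.aligned_seq = row.aligned_seq[:off] + "-" * count + row.aligned_seq[off:]
            row.aligned_quals = row.aligned_quals[:off] + [None] * count + row.aligned_quals[off:]


def align_cluster(cluster: list[QualityRead], cfg: AssemblyConfig | None = None,
                  contig_id: str = "contig") -> tuple[Contig | None, list[QualityRead]]:
    """Star alignment of a cluster: longest member seeds, others join the
    evolving consensus.  Returns the contig (None if fewer than two members
    survive) and any demoted members."""
    cfg = cfg or AssemblyConfig()
    if len(cluster) < 2:
        raise ValueError("align_cluster needs a cluster of size >= 2")
    ordered = sorted(cluster, key=lambda r: (-len(r.bases), r.read_id))
    aligner = _aligner(cfg)
    seed = ordered[0]
    contig = Contig(contig_id, [AlignedRead(seed.read_id, "+", 0, seed.bases, list(seed.quals))])
    call_consensus(contig)
    demoted: list[QualityRead] = []
    for read in ordered[1:]:
        if not _merge_read(contig, read, cfg, aligner):
            demoted.append(read)
            continue
        call_consensus(contig)
    if len(contig.rows) < 2:
        leftover = [r for r in ordered if r.read_id in {row.read_id for row in contig.rows}]
        return None, demoted + leftover
    return contig, demoted


def _merge_read(contig: Contig, read: QualityRead, cfg: AssemblyConfig, aligner) -> bool:
    hit = _best_overlap(contig.consensus, read.bases, cfg, aligner)
    if hit is None:
        return False
    identity, columns, orientation, aln = hit
    if columns < cfg.min_overlap_length or identity < cfg.min_overlap_identity:
        return False
    bases = read.bases if orientation == "+" else revcomp(read.bases)
    quals = list(read.quals) if orientation == "+" else list(read.quals)[::-1]
    _, _, pairs = _alignment_stats(aln)
    (t0, _), (q0, _) = pairs[0]
    (_, t_end), (_, q_end) = pairs[-1]
    ncols = len(contig.consensus)

    # interior unaligned overhangs signal a poor join
    left_clip = q0 if t0 > 0 else 0
    right_clip = (len(bases) - q_end) if t_end < ncols else 0
    if max(left_clip, right_clip) > cfg.max_unaligned_overhang:
        return False

    inserts: list[tuple[int, int]] = []   # (column, count) in current coords
    seq_parts: list[str] = []
    qual_parts: list[list[int | None]] = []
    if t0 == 0 and q0 > 0:                # extend contig to the left
        inserts.append((0, q0))
        seq_parts.append(bases[:q0])
        qual_parts.append(quals[:q0])
        start_col = 0
    else:                                  # clip any unaligned prefix
        start_col = t0
    prev_t = prev_q = None
    for (bt0, bt1), (bq0, bq1) in pairs:
        if prev_t is not None:
            if bt0 > prev_t:               # gap in read
                seq_parts.append("-" * (bt0 - prev_t))
                qual_parts.append([None] * (bt0 - prev_t))
            if bq0 > prev_q:               # insertion: new columns for the read
                inserts.append((prev_t, bq0 - prev_q))
                seq_parts.append(bases[prev_q:bq0])
                qual_parts.append(quals[prev_q:bq0])
        seq_parts.append(bases[bq0:bq1])
        qual_parts.append(quals[bq0:bq1])
        prev_t, prev_q = bt1, bq1
    if t_end == ncols and q_end < len(bases):  # extend to the right
        seq_parts.append(bases[q_end:])
        qual_parts.append(quals[q_end:])

    for col, count in sorted(inserts, reverse=True):
        _insert_columns(contig.rows, col, count)
    aligned_seq = "".join(seq_parts)
    aligned_quals = [q for part in qual_parts for q in part]
    contig.rows.append(AlignedRead(read.read_id, orientation, start_col,
                                   aligned_seq, aligned_quals))
    return True


def call_consensus(contig: Contig) -> tuple[str, list[int]]:
    """Quality-weighted consensus: per column, each base scores the summed
    Phred of its supporting reads; the winner is called with quality equal to
    its margin over the runner-up (capped at 93).  Ties break alphabetically
    and are flagged.  All-gap columns cannot arise during star alignment but
    are skipped defensively."""
    scores, counts, depth, _ = column_profile(contig)
    all_gap = np.flatnonzero((depth == 0) & (counts.sum(axis=1) == 0))
    if all_gap.size:
        for col in reversed(all_gap.tolist()):
            _remove_column(contig, col)
        scores, counts, depth, _ = column_profile(contig)
    ncols = scores.shape[0]
    present = counts > 0
    # argmax over A,C,G,T gives the alphabetical winner on score ties
    winner_idx = np.argmax(scores, axis=1)
    top = scores[np.arange(ncols), winner_idx]
    masked = scores.copy()
    masked[np.arange(ncols), winner_idx] = np.iinfo(np.int64).min
    runner = np.max(masked, axis=1)
    runner = np.where(runner == np.iinfo(np.int64).min, 0, runner)
    n_top = ((scores == top[:, None]) & present).sum(axis=1)
    consensus = np.array(list("ACGT"))[winner_idx]
    consensus[~present.any(axis=1)] = "N"
    quals = np.minimum(93, top - np.maximum(runner, 0))
    quals[~present.any(axis=1)] = 0
    contig.consensus = "".join(consensus.tolist())
    contig.consensus_quals = [int(q) for q in quals]
    contig.tie_columns = set(np.flatnonzero(n_top >= 2).tolist())
    return contig.consensus, contig.consensus_quals


_BASE_BYTES = (ord("A"), ord("C"), ord("G"), ord("T"))


def column_profile(contig: Contig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (quality scores, base counts, non-gap depth, any-gap flag)
    over the alphabet A,C,G,T."""
    ncols = contig.n_columns
    scores = np.zeros((ncols, 4), dtype=np.int64)
    counts = np.zeros((ncols, 4), dtype=np.int64)
    depth = np.zeros(ncols, dtype=np.int64)
    gap_any = np.zeros(ncols, dtype=bool)
    for row in contig.rows:
        codes = np.frombuffer(row.aligned_seq.encode("ascii"), dtype=np.uint8)
        quals = np.array([0 if q is None else q for q in row.aligned_quals], dtype=np.int64)
        cols = np.arange(row.start_col, row.end_col)
        gaps = codes == ord("-")
        gap_any[cols[gaps]] = True
        depth[cols[~gaps]] += 1
        for bi, byte in enumerate(_BASE_BYTES):
            mask = codes == byte
            if mask.any():
                scores[cols[mask], bi] += quals[mask]
                counts[cols[mask], bi] += 1
    return scores, counts, depth, gap_any


def _remove_column(contig: Contig, col: int) -> None:
    for row in contig.rows:
        if col < row.start_col:
            row.start_col -= 1
        elif col < row.end_col:
            off = col - row.start_col
            row.aligned_seq = row.aligned_seq[:off] + row.aligned_seq[off + 1:]
            row.aligned_quals = row.aligned_quals[:off] + row.aligned_quals[off + 1:]


def assemble(reads: list[QualityRead], cfg: AssemblyConfig | None = None
             ) -> tuple[list[Contig], list[QualityRead]]:
    """Cluster reads and build one contig per multi-read cluster.

    Returns (contigs, singlets); demoted members join the singlets.
    """
    cfg = cfg or AssemblyConfig()
    clusters, singlets = cluster_reads(reads, cfg)
    contigs: list[Contig] = []
    all_singlets = list(singlets)
    for i, cluster in enumerate(clusters):
        contig, demoted = align_cluster(cluster, cfg, contig_id=f"contig{i + 1:05d}")
        all_singlets.extend(demoted)
        if contig is not None:
            contigs.append(contig)
    return contigs, all_singlets
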