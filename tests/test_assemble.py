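"""Clustering, star alignment and quality-weighted consensus."""

import numpy as np
import pytest

from estsnp.assemble import (AssemblyConfig, align_cluster, assemble,
                             call_consensus, cluster_reads)
from estsnp.preprocess import QualityRead, revcomp, trim_reads
from estsnp.pipeline import RunConfig

from conftest import make_contig, read

RNG = np.random.default_rng(777)
BASE = "".join(RNG.choice(list("ACGT"), size=300))


def test_identical_reads_form_one_cluster():
    clusters, singlets = cluster_reads([read("a", BASE), read("b", BASE)])
    assert len(clusters) == 1 and len(clusters[0]) == 2 and not singlets


@pytest.mark.parametrize("n_mismatch,expect_cluster", [(8, False), (6, True)])
def test_overlap_identity_cutoff(n_mismatch, expect_cluster):
    """100-bp overlap at 92% identity splits, 94% joins, under the 93% cutoff."""
    overlap = BASE[100:200]
    mutated = list(overlap)
    for k in range(n_mismatch):           # interior, evenly spread
        pos = 8 + k * 11
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    read_a = read("a", BASE[:200])                       # ...ends with overlap
    read_b = read("b", "".join(mutated) + BASE[200:])    # starts with mutated overlap
    clusters, singlets = cluster_reads([read_a, read_b])
    if expect_cluster:
        assert len(clusters) == 1 and not singlets
    else:
        assert not clusters and len(singlets) == 2


def test_reverse_complement_read_clusters():
    clusters, _ = cluster_reads([read("a", BASE), read("b", revcomp(BASE))])
    assert len(clusters) == 1


def test_removing_a_singlet_leaves_clusters_unchanged():
    other = "".join(RNG.choice(list("ACGT"), size=250))
    reads = [read("a", BASE), read("b", BASE[50:]), read("x", other)]
    with_x, singlets = cluster_reads(reads)
    without_x, _ = cluster_reads(reads[:2])
    assert [r.read_id for r in singlets] == ["x"]
    assert [[r.read_id for r in c] for c in with_x] == \
           [[r.read_id for r in c] for c in without_x]


def test_one_mismatch_alignment_has_no_pads():
    variant = BASE[:150] + ("A" if BASE[150] != "A" else "C") + BASE[151:]
    contig, demoted = align_cluster([read("a", BASE), read("b", variant)])
    assert not demoted
    assert all("-" not in row.aligned_seq for row in contig.rows)
    assert len(contig.consensus) == len(BASE)


def test_deletion_creates_gap_column():
    shorter = BASE[:150] + BASE[151:]      # one base deleted
    contig, _ = align_cluster([read("a", BASE), read("b", shorter)])
    gap_cols = contig.gap_columns()
    assert len(gap_cols) == 1
    assert len(contig.consensus) == len(BASE)


def test_consensus_quality_weighted_majority():
    contig = make_contig([("a", 0, "A", 30), ("b", 0, "A", 30), ("c", 0, "G", 10)])
    assert contig.consensus == "A"
    assert contig.consensus_quals == [50]


def test_consensus_tie_breaks_alphabetically_and_flags():
    contig = make_contig([("a", 0, "G", 20), ("b", 0, "A", 20)])
    assert contig.consensus == "A"
    assert contig.tie_columns == {0}
    assert contig.consensus_quals == [0]


def test_consensus_invariant_under_member_permutation(rng):
    rows = [("a", 0, BASE[:60], 30), ("b", 10, BASE[10:70], 25),
            ("c", 20, BASE[20:80], 35)]
    base_contig = make_contig(rows)
    for _ in range(3):
        perm = [rows[i] for i in rng.permutation(3)]
        assert make_contig(perm).consensus == base_contig.consensus


def test_zero_error_assembly_recovers_genes(small_zero_error_library):
    """Clusters correspond 1:1 to overlap-connected gene read groups, and each
    consensus matches its source gene over the covered interval.

    The expectation comes from an independent interval-overlap union-find on
    the truth table, not from the assembler."""
    reads, truth = small_zero_error_library
    cfg = RunConfig()
    trimmed, _ = trim_reads(reads, cfg.trim)
    contigs, singlets = assemble(trimmed, cfg.assembly)

    # oracle: group truth windows per gene by >=40bp interval overlap
    expected_groups = 0
    for gene_id in truth.genes:
        provs = [p for p in truth.provenance if p.gene_id == gene_id]
        windows = [truth.gene_window(p) for p in provs]
        windows = [w for w in windows if w[1] - w[0] >= 50]
        parent = list(range(len(windows)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                lo = max(windows[i][0], windows[j][0])
                hi = min(windows[i][1], windows[j][1])
                if hi - lo >= 40:
                    parent[find(i)] = find(j)
        sizes = {}
        for i in range(len(windows)):
            sizes[find(i)] = sizes.get(find(i), 0) + 1
        expected_groups += sum(1 for s in sizes.values() if s >= 2)

    assert len(contigs) == expected_groups

    # consensus equals the gene over the covered interval (either strand),
    # apart from planted SNP columns where either allele may win
    from estsnp.evaluation import map_contig_to_gene
    snp_positions = {(s.gene_id, s.position)
                     for s in truth.planted_snps + truth.unrealized_snps}
    for contig in contigs:
        mapping = map_contig_to_gene(contig, truth)
        assert mapping is not None
        gene_id, offset, direction = mapping
        gene = truth.genes[gene_id] + "A" * truth.polya_lengths[gene_id]
        for col, base in enumerate(contig.consensus):
            pos = offset + direction * col
            if not 0 <= pos < len(gene):
                continue
            expected = gene[pos] if direction == 1 else revcomp(gene[pos])
            if base != expected:
                assert (gene_id, pos) in snp_positions


def test_config_validation():
    with pytest.raises(ValueError):
        AssemblyConfig(min_overlap_identity=40)
    with pytest.raises(ValueError):
        AssemblyConfig(min_overlap_length=5)


def test_all_n_column_called_as_n():
    contig = make_contig([("a", 0, "N", 30), ("b", 0, "N", 30)])
    assert contig.consensus == "N"
    assert contig.consensus_quals == [0]
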