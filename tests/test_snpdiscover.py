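"""Detector voting, filter cascade and marker selection."""

import numpy as np
import pytest

from estsnp.assemble import assemble
from estsnp.evaluation import score_discovery
from estsnp.pipeline import RunConfig
from estsnp.preprocess import trim_reads
from estsnp.snpdiscover import (DiscoveryConfig, apply_filters, discover_snps,
                                run_detectors, scan_columns, select_markers)

from conftest import make_contig

RNG = np.random.default_rng(99)
SEQ = "".join(RNG.choice(list("ACGT"), size=400))
CFG = DiscoveryConfig()


def other_base(ref: str, shift: int = 1) -> str:
    return "ACGT"[("ACGT".index(ref) + shift) % 4]


def snp_contig(column=200, minor=None, minor_rows=(2, 3), depth=4, q=40,
               minor_q=None, length=400):
    """Depth-``depth`` contig, fully overlapping reads, one variant column."""
    minor = minor or other_base(SEQ[column])
    rows = []
    for i in range(depth):
        seq = list(SEQ[:length])
        quals = [q] * length
        if i in minor_rows:
            seq[column] = minor
            if minor_q is not None:
                quals[column] = minor_q
        rows.append((f"r{i}", 0, "".join(seq), quals))
    return make_contig(rows)


def test_depth_floor_blocks_scanning():
    contig = snp_contig(depth=3, minor_rows=(1,))
    assert scan_columns(contig, CFG) == []


def test_scan_emits_singleton_and_recurrent_mismatches():
    contig = snp_contig(minor_rows=(2, 3))
    (cand,) = scan_columns(contig, CFG)
    assert (cand.column, cand.minor_count, cand.depth) == (200, 2, 4)
    contig = snp_contig(minor_rows=(3,))
    (cand,) = scan_columns(contig, CFG)
    assert cand.minor_count == 1


def test_third_allele_marks_multiallelic():
    contig = snp_contig(depth=6, minor_rows=(2, 3))
    # give row 4 a third allele at the same column
    base = contig.rows[4].aligned_seq
    third = "C" if SEQ[200] not in "C" else "T"
    contig.rows[4].aligned_seq = base[:200] + third + base[201:]
    from estsnp.assemble import call_consensus
    call_consensus(contig)
    (cand,) = scan_columns(contig, CFG)
    assert cand.multiallelic


def _bayes_oracle(bases, quals, major, minor, prior=0.003):
    """Independent brute-force posterior (pure Python floats)."""
    es = [min(10 ** (-q / 10), 0.75) for q in quals]
    def prod(vals):
        out = 1.0
        for v in vals:
            out *= v
        return out
    l_mono = max(
        prod((1 - e) if b == a else e / 3 for b, e in zip(bases, es))
        for a in (major, minor))
    l_poly = max(
        prod(f * ((1 - e) if b == minor else e / 3)
             + (1 - f) * ((1 - e) if b == major else e / 3)
             for b, e in zip(bases, es))
        for f in (0.1, 0.2, 0.3, 0.4, 0.5))
    return prior * l_poly / (prior * l_poly + (1 - prior) * l_mono)


def test_clean_balanced_column_wins_all_four_votes():
    contig = snp_contig(minor_rows=(2, 3), q=40)
    (cand,) = scan_columns(contig, CFG)
    votes = run_detectors(contig, cand, [cand], CFG)
    assert votes == {"COUNT", "QUALITY", "BAYES", "HAPLO"}
    major, minor = SEQ[200], other_base(SEQ[200])
    oracle = _bayes_oracle(
        [major, major, minor, minor], [40, 40, 40, 40], major, minor)
    assert cand.bayes_posterior == pytest.approx(oracle, abs=1e-12)
    assert cand.bayes_posterior == pytest.approx(0.9999941, abs=1e-6)


def test_low_quality_minor_loses_quality_vote_only():
    contig = snp_contig(minor_rows=(2, 3), q=40, minor_q=5)
    # only one minor base is low quality: overwrite row 3's qual back to 40
    contig.rows[3].aligned_quals[200] = 40
    (cand,) = scan_columns(contig, CFG)
    votes = run_detectors(contig, cand, [cand], CFG)
    assert "QUALITY" not in votes and "COUNT" in votes


def test_haplo_withholds_on_cosegregation_break():
    """Two variant columns; the minor reads of column 1 disagree at column 2."""
    rows = []
    for i in range(4):
        seq = list(SEQ[:400])
        if i in (2, 3):
            seq[200] = "G" if SEQ[200] != "G" else "A"
        if i == 2:
            seq[250] = "C" if SEQ[250] != "C" else "T"
        if i == 1:
            seq[250] = "C" if SEQ[250] != "C" else "T"
        rows.append((f"r{i}", 0, "".join(seq), 40))
    contig = make_contig(rows)
    candidates = scan_columns(contig, CFG)
    assert len(candidates) == 2
    first = next(c for c in candidates if c.column == 200)
    votes = run_detectors(contig, first, candidates, CFG)
    assert "HAPLO" not in votes


def test_haplo_defers_to_count_without_other_columns():
    contig = snp_contig(minor_rows=(2, 3))
    (cand,) = scan_columns(contig, CFG)
    assert "HAPLO" in run_detectors(contig, cand, [cand], CFG)


def test_contiguous_candidates_both_flagged():
    rows = []
    for i in range(4):
        seq = list(SEQ[:400])
        if i in (2, 3):
            seq[200] = "G" if SEQ[200] != "G" else "A"
            seq[201] = "C" if SEQ[201] != "C" else "T"
        rows.append((f"r{i}", 0, "".join(seq), 40))
    contig = make_contig(rows)
    candidates = scan_columns(contig, CFG)
    apply_filters(contig, candidates, CFG)
    assert all("CONTIGUOUS" in c.filter_flags for c in candidates)


@pytest.mark.parametrize("column,flagged", [(4, True), (69, True), (200, False),
                                            (395, True)])
def test_near_end_filter(column, flagged):
    contig = snp_contig(column=column)
    candidates = scan_columns(contig, CFG)
    apply_filters(contig, candidates, CFG)
    assert ("NEAR_END" in candidates[0].filter_flags) == flagged


@pytest.mark.parametrize("n_neighbors,flagged", [(3, False), (4, True)])
def test_poly_flank_strict_inequality(n_neighbors, flagged):
    rows = []
    positions = [200] + [210 + 12 * k for k in range(n_neighbors)]
    for i in range(4):
        seq = list(SEQ[:400])
        if i in (2, 3):
            for pos in positions:
                seq[pos] = "G" if SEQ[pos] != "G" else "A"
        rows.append((f"r{i}", 0, "".join(seq), 40))
    contig = make_contig(rows)
    candidates = scan_columns(contig, CFG)
    target = next(c for c in candidates if c.column == 200)
    apply_filters(contig, candidates, CFG)
    assert ("POLY_FLANK" in target.filter_flags) == flagged


def test_near_indel_filter():
    seq_del = SEQ[:195] + SEQ[196:400]
    rows = [("r0", 0, SEQ[:400], 40), ("r1", 0, SEQ[:400], 40),
            ("r2", 0, SEQ[:400], 40)]
    contig, demoted = None, None
    from estsnp.assemble import align_cluster
    from estsnp.preprocess import QualityRead
    reads = [QualityRead("r0", SEQ[:400], [40] * 400),
             QualityRead("r1", SEQ[:400], [40] * 400),
             QualityRead("r2", seq_del, [40] * len(seq_del)),
             QualityRead("r3", SEQ[:400], [40] * 400)]
    # plant a SNP within 10 columns of the deletion
    snp = list(SEQ[:400])
    snp[203] = "G" if SEQ[203] != "G" else "A"
    reads.append(QualityRead("r4", "".join(snp), [40] * 400))
    snp2 = "".join(snp)
    reads.append(QualityRead("r5", snp2, [40] * 400))
    contig, _ = align_cluster(reads)
    candidates = scan_columns(contig, CFG)
    target = next(c for c in candidates if c.minor_count >= 2)
    apply_filters(contig, candidates, CFG)
    assert "NEAR_INDEL" in target.filter_flags


def test_selection_prefers_votes_then_minor_count():
    # two co-segregating variant columns carried by the same reads; the
    # second loses the QUALITY vote through one q=5 minor base
    contig = snp_contig(depth=6, minor_rows=(4, 5), column=150)
    for i in (4, 5):
        s = list(contig.rows[i].aligned_seq)
        s[250] = other_base(s[250])
        contig.rows[i].aligned_seq = "".join(s)
    contig.rows[4].aligned_quals[250] = 5
    from estsnp.assemble import call_consensus
    call_consensus(contig)
    candidates = scan_columns(contig, CFG)
    for cand in candidates:
        run_detectors(contig, cand, candidates, CFG)
    apply_filters(contig, candidates, CFG)
    selected = select_markers(candidates, CFG)
    assert len(selected) == 1
    assert selected[0].column == 150
    assert len(selected[0].votes) == 4


def test_contig_without_survivors_reports_snp_free():
    contig = snp_contig(column=4)      # NEAR_END kills the only candidate
    candidates = scan_columns(contig, CFG)
    for cand in candidates:
        run_detectors(contig, cand, candidates, CFG)
    apply_filters(contig, candidates, CFG)
    assert select_markers(candidates, CFG) == []


def test_raising_min_votes_never_grows_selection(small_zero_error_library):
    reads, _ = small_zero_error_library
    cfg = RunConfig()
    trimmed, _ = trim_reads(reads, cfg.trim)
    contigs, _ = assemble(trimmed, cfg.assembly)
    previous = None
    for min_votes in (1, 2, 3, 4):
        dcfg = DiscoveryConfig(min_votes=min_votes)
        _, selected = discover_snps(contigs, dcfg)
        keys = {(c.contig_id, c.column) for c in selected}
        contigs_hit = {c.contig_id for c in selected}
        assert len(contigs_hit) == len(selected)      # one per contig
        if previous is not None:
            assert {k[0] for k in keys} <= {k[0] for k in previous} or \
                len(keys) <= len(previous)
        previous = keys


def test_zero_error_recovery_on_small_library(small_zero_error_library):
    """Accepted candidates recover >=90% of discoverable planted SNPs with no
    false selections on error-free data (truth-table oracle)."""
    reads, truth = small_zero_error_library
    cfg = RunConfig()
    trimmed, _ = trim_reads(reads, cfg.trim)
    contigs, _ = assemble(trimmed, cfg.assembly)
    candidates, selected = discover_snps(contigs, cfg.discovery)
    for cand in selected:
        assert cand.minor_count >= 2 and cand.depth >= 4
    score = score_discovery(contigs, candidates, selected, truth)
    assert score.n_discoverable > 10
    assert score.sensitivity >= 0.9
    assert score.n_false_selected == 0


def test_zero_quality_bases_are_uninformative_for_bayes():
    """With every base at q=0 (error probability capped at 0.75) the data
    carry no evidence, so the posterior stays near the small prior and the
    Bayesian detector withholds."""
    contig = snp_contig(minor_rows=(2, 3), q=0)
    (cand,) = scan_columns(contig, CFG)
    votes = run_detectors(contig, cand, [cand], CFG)
    assert "BAYES" not in votes
    assert cand.bayes_posterior < 0.05
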