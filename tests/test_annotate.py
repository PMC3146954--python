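"""ORF prediction, S/NS annotation, substitution spectrum, assay risk."""

import numpy as np
import pytest

from estsnp.annotate import (annotate_marker, assess_assay_risk, build_spectrum,
                             classify_tstv, predict_orf)
from estsnp.preprocess import revcomp
from estsnp.snpdiscover import SNPCandidate
from estsnp.synthgen import PhredProfile, generate_est_library

# independent, hand-written standard genetic code (oracle for S/NS calls)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def candidate(column, major, minor, contig_id="c1"):
    return SNPCandidate(contig_id, column, major, minor, depth=6,
                        minor_count=2, major_count=4,
                        mean_major_qual=40, mean_minor_qual=40)


def orf_consensus(codon, frame_codon_index=10, n_codons=40):
    """Consensus with one planted ORF whose codon ``frame_codon_index`` is
    ``codon``; returns (consensus, orf column of the codon start)."""
    filler = "GCT"
    body = filler * frame_codon_index + codon + filler * (n_codons - frame_codon_index - 1)
    consensus = "CCTCC" + "TAACTAACTAA" + "ATG" + body + "TAA" + "CCTCC"
    start = 5 + 11
    codon_col = start + 3 + 3 * frame_codon_index
    return consensus, codon_col


def test_short_orf_needs_lower_floor():
    seq = "CCCCC" + "ATGAAATTTGGGTAG" + "CCCCC"
    assert predict_orf(seq, min_codons=30) is None
    orf = predict_orf(seq, min_codons=3)
    assert orf is not None and orf.n_codons == 4 and orf.strand == "+"


def test_orf_recovered_on_synthetic_genes():
    _, truth = generate_est_library(10, 1, 0.0, PhredProfile(93, 93), seed=6)
    for gene_id, seq in truth.genes.items():
        orf = predict_orf(seq)
        assert orf is not None
        assert (orf.start, orf.end) == truth.orfs[gene_id]


def test_orf_reverse_strand_frames():
    _, truth = generate_est_library(5, 1, 0.0, PhredProfile(93, 93), seed=8)
    for gene_id, seq in truth.genes.items():
        orf = predict_orf(revcomp(seq))
        start, end = truth.orfs[gene_id]
        assert orf.frame >= 4
        assert (len(seq) - orf.end, len(seq) - orf.start) == (start, end)


@pytest.mark.parametrize("codon,pos,alt,expected_class,expected_aa", [
    ("GAA", 3, "G", "S", ("E", "E")),      # GAA -> GAG, Glu = Glu
    ("GAA", 2, "G", "NS", ("E", "G")),     # GAA -> GGA, Glu -> Gly
    ("TTA", 1, "C", "NS", ("L", "L")),     # oops: TTA->CTA is Leu->Leu (S)
])
def test_codon_classification_examples(codon, pos, alt, expected_class, expected_aa):
    consensus, codon_col = orf_consensus(codon)
    col = codon_col + pos - 1
    major = consensus[col]
    marker = annotate_marker(consensus, candidate(col, major, alt),
                             predict_orf(consensus))
    oracle_ref = GENETIC_CODE[codon]
    oracle_alt = GENETIC_CODE[codon[:pos - 1] + alt + codon[pos:]]
    assert marker.codon_position == pos
    assert marker.aa_change == (oracle_ref, oracle_alt)
    assert marker.substitution_class == ("S" if oracle_ref == oracle_alt else "NS")


def test_genetic_code_consistency_all_codons():
    """Every codon x position x alternative agrees with the hand-built code
    table; in particular every fourfold-degenerate third position is S."""
    for c1 in "ACGT":
        for c2 in "ACGT":
            for c3 in "ACGT":
                codon = c1 + c2 + c3
                if GENETIC_CODE[codon] == "*":
                    continue      # a planted stop truncates the reading frame
                consensus, codon_col = orf_consensus(codon)
                orf = predict_orf(consensus)
                for pos in (1, 2, 3):
                    col = codon_col + pos - 1
                    ref_base = codon[pos - 1]
                    for alt in "ACGT":
                        if alt == ref_base:
                            continue
                        marker = annotate_marker(
                            consensus, candidate(col, ref_base, alt), orf)
                        alt_codon = codon[:pos - 1] + alt + codon[pos:]
                        same = GENETIC_CODE[codon] == GENETIC_CODE[alt_codon]
                        assert marker.codon_position == pos
                        assert marker.substitution_class == ("S" if same else "NS")


def test_fourfold_degenerate_third_positions_synonymous():
    fourfold = ["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"]
    for stem in fourfold:
        aas = {GENETIC_CODE[stem + b] for b in "ACGT"}
        assert len(aas) == 1      # sanity of the oracle table itself


@pytest.mark.parametrize("a,b,expected", [
    ("A", "G", "transition"), ("C", "T", "transition"),
    ("A", "T", "transversion"), ("A", "C", "transversion"),
    ("C", "G", "transversion"), ("G", "T", "transversion"),
])
def test_transition_transversion(a, b, expected):
    assert classify_tstv(a, b) == expected


def test_marker_outside_orf_is_noncoding():
    consensus, _ = orf_consensus("GAA")
    marker = annotate_marker(consensus, candidate(2, consensus[2], "A" if consensus[2] != "A" else "C"),
                             predict_orf(consensus))
    assert marker.substitution_class == "noncoding"
    assert marker.codon_position is None


def test_flank_iupac_encoding_and_count():
    consensus, codon_col = orf_consensus("GAA", n_codons=80)
    col = codon_col
    variant_alleles = {col: ("G", "A"), col - 10: ("A", "G"), col + 7: ("C", "T"),
                       col + 100: ("A", "T")}
    marker = annotate_marker(consensus, candidate(col, consensus[col], "A"),
                             predict_orf(consensus), variant_alleles,
                             flank_window=70)
    assert marker.flank5[-10] == "R"            # A/G ambiguity 10 left of site
    assert marker.flank3[6] == "Y"              # C/T ambiguity 7 right of site
    assert marker.flank_polymorphism_count == 2  # the +100 one is outside


@pytest.mark.parametrize("count,risk", [(0, "low"), (3, "low"), (4, "high")])
def test_assay_risk_boundary(count, risk):
    consensus, codon_col = orf_consensus("GAA", n_codons=80)
    variant_alleles = {codon_col + 2 + k: ("A", "G") for k in range(count)}
    marker = annotate_marker(consensus, candidate(codon_col, consensus[codon_col], "A"),
                             predict_orf(consensus), variant_alleles)
    assert marker.flank_polymorphism_count == count
    assert marker.assay_risk == risk


def test_spectrum_counts_and_percentages():
    consensus, codon_col = orf_consensus("GAA")
    orf = predict_orf(consensus)
    markers = [
        annotate_marker(consensus, candidate(codon_col + 2, consensus[codon_col + 2], "G"), orf),
        annotate_marker(consensus, candidate(codon_col + 1, consensus[codon_col + 1], "G"), orf),
        annotate_marker(consensus, candidate(2, consensus[2],
                                             "A" if consensus[2] != "A" else "C"), orf),
    ]
    table = build_spectrum(markers)
    assert table.n_markers == 3
    assert table.n_coding == 2
    assert int(table.codon_counts.to_numpy().sum()) == 2
    frame = table.to_frame()
    assert frame.loc[frame.category == "markers", "count"].item() == 3


def test_spectrum_empty():
    table = build_spectrum([])
    assert table.n_markers == 0
    assert (table.codon_counts.to_numpy() == 0).all()


def test_annotation_is_pure():
    consensus, codon_col = orf_consensus("GAA")
    orf = predict_orf(consensus)
    a = annotate_marker(consensus, candidate(codon_col, consensus[codon_col], "A"), orf)
    b = annotate_marker(consensus, candidate(codon_col, consensus[codon_col], "A"), orf)
    assert a == b
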