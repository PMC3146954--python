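"""Functional characterisation of selected SNPs.

Each marker is placed in the longest open reading frame of its contig
consensus (six-frame scan), classified by codon position and synonymous /
non-synonymous status under the standard nuclear genetic code, typed as a
transition or transversion, and packaged with its 70-bp assay flanks in
which every other polymorphic column is written as an IUPAC ambiguity code.
A flank carrying more than three other polymorphisms marks the assay as
high-risk, mirroring the observation that probe-flank polymorphism predicts
genotyping failure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .preprocess import revcomp
from .snpdiscover import SNPCandidate

__all__ = ["ORF", "SNPMarker", "SpectrumTable", "predict_orf",
           "annotate_marker", "build_spectrum", "assess_assay_risk"]

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass
class ORF:
    """Longest ATG..stop span; coordinates on the consensus, half-open,
    including the stop codon.  Frames 1-3 are forward, 4-6 reverse."""

    frame: int
    start: int
    end: int
    n_codons: int          # coding codons, stop excluded

    @property
    def strand(self) -> str:
        return "+" if self.frame <= 3 else "-"


def _scan_frames(seq: str, min_codons: int):
    """Yield (frame_offset, start, end, n_codons) for ATG..stop spans in the
    three forward frames of ``seq``."""
    for offset in range(3):
        start = None
        for pos in range(offset, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if start is not None:
                    n = (pos - start) // 3
                    if n >= min_codons:
                        yield offset, start, pos + 3, n
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        # open spans without a stop are not reported


def predict_orf(consensus: str, min_codons: int = 30) -> ORF | None:
    """Longest ORF across six frames, or None.

    Ties break by frame order (1-6) then by the leftmost start in the scanned
    strand; the floor of ``min_codons`` coding codons filters spurious short
    frames.
    """
    if len(consensus) < 3:
        return None
    length = len(consensus)
    best: ORF | None = None
    for strand_idx, seq in enumerate((consensus, revcomp(consensus))):
        for offset, start, end, n in _scan_frames(seq, min_codons):
            frame = strand_idx * 3 + offset + 1
            if strand_idx == 0:
                orf = ORF(frame, start, end, n)
            else:
                orf = ORF(frame, length - end, length - start, n)
            if best is None or n > best.n_codons:
                best = orf
    return best


@dataclass
class SNPMarker:
    candidate: SNPCandidate
    contig_id: str
    column: int
    orf: ORF | None
    codon_position: int | None          # 1..3, None outside any ORF
    substitution_class: str             # 'S' | 'NS' | 'noncoding'
    aa_change: tuple[str, str] | None   # (ref AA, alt AA) when inside an ORF
    tstv: str                           # 'transition' | 'transversion'
    flank5: str
    flank3: str
    flank_polymorphism_count: int
    assay_risk: str = "low"


def classify_tstv(a: str, b: str) -> str:
    return "transition" if {a, b} in _TRANSITIONS else "transversion"


def _iupac_encode(consensus: str, lo: int, hi: int,
                  variant_alleles: dict[int, tuple[str, str]], skip: int) -> str:
    chars = list(consensus[lo:hi])
    for col, pair in variant_alleles.items():
        if lo <= col < hi and col != skip:
            code = _IUPAC.get(frozenset(pair))
            if code:
                chars[col - lo] = code
    return "".join(chars)


def annotate_marker(consensus: str, candidate: SNPCandidate, orf: ORF | None,
                    variant_alleles: dict[int, tuple[str, str]] | None = None,
                    flank_window: int = 70,
                    max_flank_polymorphisms: int = 3) -> SNPMarker:
    """Attach ORF/codon/substitution/flank annotation to a selected candidate.

    ``variant_alleles`` maps every other polymorphic consensus column of the
    contig to its allele pair (used for IUPAC flank encoding and the flank
    polymorphism count).
    """
    variant_alleles = variant_alleles or {}
    col = candidate.column
    major, minor = candidate.major_allele, candidate.minor_allele

    codon_position = None
    substitution = "noncoding"
    aa_change = None
    if orf is not None and orf.start <= col < orf.end:
        if orf.strand == "+":
            cds = consensus[orf.start : orf.end]
            offset = col - orf.start
            ref_allele, alt_allele = major, minor
        else:
            cds = revcomp(consensus)[len(consensus) - orf.end : len(consensus) - orf.start]
            offset = (len(consensus) - 1 - col) - (len(consensus) - orf.end)
            ref_allele, alt_allele = _COMPLEMENT[major], _COMPLEMENT[minor]
        codon_position = offset % 3 + 1
        ci = offset - offset % 3
        ref_codon = list(cds[ci : ci + 3])
        alt_codon = list(ref_codon)
        ref_codon[offset % 3] = ref_allele
        alt_codon[offset % 3] = alt_allele
        ref_aa = str(Seq("".join(ref_codon)).translate())
        alt_aa = str(Seq("".join(alt_codon)).translate())
        substitution = "S" if ref_aa == alt_aa else "NS"
        aa_change = (ref_aa, alt_aa)

    lo5, hi5 = max(0, col - flank_window), col
    lo3, hi3 = col + 1, min(len(consensus), col + 1 + flank_window)
    flank5 = _iupac_encode(consensus, lo5, hi5, variant_alleles, skip=col)
    flank3 = _iupac_encode(consensus, lo3, hi3, variant_alleles, skip=col)
    n_poly = sum(1 for c in variant_alleles
                 if c != col and abs(c - col) <= flank_window)

    marker = SNPMarker(
        candidate=candidate,
        contig_id=candidate.contig_id,
        column=col,
        orf=orf,
        codon_position=codon_position,
        substitution_class=substitution,
        aa_change=aa_change,
        tstv=classify_tstv(major, minor),
        flank5=flank5,
        flank3=flank3,
        flank_polymorphism_count=n_poly,
    )
    marker.assay_risk = assess_assay_risk(marker, max_flank_polymorphisms)
    return marker


def assess_assay_risk(marker: SNPMarker, max_flank_polymorphisms: int = 3) -> str:
    """'high' when strictly more than the allowed flank polymorphisms."""
    return "high" if marker.flank_polymorphism_count > max_flank_polymorphisms else "low"


@dataclass
class SpectrumTable:
    """Codon-position by S/NS counts plus the six substitution types."""

    codon_counts: pd.DataFrame          # index 1..3, columns S/NS
    substitution_counts: "Counter[str]"
    n_markers: int
    n_coding: int

    def codon_position_percent(self) -> dict[int, float]:
        totals = self.codon_counts.sum(axis=1)
        denom = self.n_coding or 1
        return {int(pos): 100.0 * n / denom for pos, n in totals.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in (1, 2, 3):
            for cls in ("S", "NS"):
                rows.append(("codon_position", f"{pos}:{cls}",
                             int(self.codon_counts.loc[pos, cls])))
        for pair in ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T"):
            rows.append(("substitution", pair, self.substitution_counts.get(pair, 0)))
        rows.append(("total", "markers", self.n_markers))
        rows.append(("total", "coding", self.n_coding))
        return pd.DataFrame(rows, columns=["panel", "category", "count"])


def build_spectrum(markers: list[SNPMarker]) -> SpectrumTable:
    codon = pd.DataFrame(0, index=[1, 2, 3], columns=["S", "NS"])
    subst: Counter[str] = Counter()
    n_coding = 0
    for m in markers:
        pair = "/".join(sorted((m.candidate.major_allele, m.candidate.minor_allele)))
        subst[pair] += 1
        if m.codon_position is not None and m.substitution_class in ("S", "NS"):
            codon.loc[m.codon_position, m.substitution_class] += 1
            n_coding += 1
    return SpectrumTable(codon, subst, n_markers=len(markers), n_coding=n_coding)
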