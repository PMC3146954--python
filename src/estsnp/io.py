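"""File formats: FASTA(+QUAL) reads, ACE assemblies, VCF markers, TSV tables.

FASTA and QUAL go through Biopython; VCF through pysam; tabular outputs
through pandas.  ACE output is written directly (standard AS/CO/BQ/AF/RD/QA
records) since no maintained Python library writes ACE.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import QualityRead

if TYPE_CHECKING:  # pragma: no cover
    from .assemble import Contig

__all__ = [
    "read_fasta_qual",
    "write_fasta_qual",
    "write_ace",
    "write_marker_vcf",
    "write_tsv",
]


def read_fasta_qual(fasta_path: str, qual_path: str | None = None,
                    library_tag: str = "") -> list[QualityRead]:
    """Load reads from a FASTA file, with Phred scores from a companion QUAL
    file when given (record order and ids must match)."""
    seqs = list(SeqIO.parse(fasta_path, "fasta"))
    if qual_path is None:
        return [QualityRead(r.id, str(r.seq).upper(), [0] * len(r.seq),
                            library_tag, quals_imputed=True) for r in seqs]
    quals = SeqIO.to_dict(SeqIO.parse(qual_path, "qual"))
    reads = []
    for rec in seqs:
        try:
            q = quals[rec.id].letter_annotations["phred_quality"]
        except KeyError:
            raise ValueError(f"no quality record for read {rec.id!r}") from None
        reads.append(QualityRead(rec.id, str(rec.seq).upper(), list(q), library_tag))
    return reads


def write_fasta_qual(reads: Iterable[QualityRead], fasta_path: str,
                     qual_path: str | None = None) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.quals)
        records.append(rec)
    SeqIO.write(records, fasta_path, "fasta")
    if qual_path is not None:
        SeqIO.write(records, qual_path, "qual")


def write_tsv(frame: pd.DataFrame, path: str, **kwargs) -> None:
    frame.to_csv(path, sep="\t", index=False, **kwargs)


def write_ace(contigs: list["Contig"], path: str) -> None:
    """Write a padded assembly as a standard ACE file (gaps become ``*``)."""
    total_reads = sum(len(c.rows) for c in contigs)
    with open(path, "w") as fh:
        fh.write(f"AS {len(contigs)} {total_reads}\n\n")
        for contig in contigs:
            padded = contig.padded_consensus().replace("-", "*")
            fh.write(f"CO {contig.contig_id} {len(padded)} {len(contig.rows)} 1 U\n")
            for i in range(0, len(padded), 60):
                fh.write(padded[i : i + 60] + "\n")
            fh.write("\nBQ\n")
            quals = " ".join(str(q) for q in contig.padded_consensus_quals())
            fh.write(quals + "\n\n")
            for row in contig.rows:
                strand = "C" if row.strand == "-" else "U"
                fh.write(f"AF {row.read_id} {strand} {row.start_col + 1}\n")
            fh.write("\n")
            for row in contig.rows:
                seq = row.aligned_seq.replace("-", "*")
                fh.write(f"RD {row.read_id} {len(seq)} 0 0\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
                fh.write(f"QA 1 {len(seq)} 1 {len(seq)}\n\n")


def write_marker_vcf(markers, contigs: list["Contig"], path: str) -> None:
    """Write selected SNP markers as an uncompressed VCF.

    CHROM is the contig id, POS the 1-based consensus coordinate, REF the
    major and ALT the minor allele; INFO carries depth, minor count and the
    detector votes.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=estsnp')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Reads covering the column">')
    header.add_line('##INFO=<ID=MC,Number=1,Type=Integer,Description="Minor-allele read count">')
    header.add_line('##INFO=<ID=VOTES,Number=.,Type=String,Description="Detectors voting for the site">')
    by_id = {c.contig_id: c for c in contigs}
    for contig in contigs:
        header.contigs.add(contig.contig_id, length=len(contig.consensus))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for m in sorted(markers, key=lambda m: (m.contig_id, m.column)):
            if m.contig_id not in by_id:
                continue
            rec = vcf.new_record(
                contig=m.contig_id,
                start=m.column,
                stop=m.column + 1,
                alleles=(m.major_allele, m.minor_allele),
            )
            rec.info["DP"] = m.depth
            rec.info["MC"] = m.minor_count
            rec.info["VOTES"] = tuple(sorted(m.votes)) or ("NONE",)
            vcf.write(rec)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
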