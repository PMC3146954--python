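"""Published reference counts for the Daphnia magna EST-SNP panel.

The synthetic generators in this package emulate, at desk scale, the marker
panel originally developed from D. magna expressed-sequence-tag libraries
and validated in six Belgian pond populations.  The dataset's headline
counts are kept here so that derived rates (assembly redundancy, codon
position spectrum, genotyping success) can be recomputed as arithmetic
checks and quoted in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DAPHNIA_EST_FUNNEL", "FunnelCounts"]


@dataclass(frozen=True)
class FunnelCounts:
    """Counts along the EST-to-marker funnel of the reference panel."""

    processed_ests: int = 14_253
    assembled_ests: int = 10_737
    singleton_ests: int = 2_446
    contigs: int = 1_812
    two_est_contigs: int = 878
    deep_contigs: int = 574            # four or more overlapping ESTs
    candidate_snps: int = 986
    designed_markers: int = 147
    codon_position_counts: tuple[int, int, int] = (43, 49, 54)
    synonymous: int = 51
    non_synonymous: int = 96
    failed_amplification: int = 10
    low_success_rate: int = 19
    not_assayable: int = 7
    polymorphic: int = 74
    monomorphic: int = 37

    # ---- derived rates, each a plain ratio of the counts above ----

    @property
    def assembly_redundancy_pct(self) -> float:
        return 100.0 * self.assembled_ests / self.processed_ests

    @property
    def singleton_pct(self) -> float:
        return 100.0 * self.singleton_ests / self.processed_ests

    @property
    def two_est_contig_pct(self) -> float:
        return 100.0 * self.two_est_contigs / self.contigs

    def codon_position_pct(self) -> tuple[float, float, float]:
        d = self.designed_markers
        c1, c2, c3 = self.codon_position_counts
        return (100.0 * c1 / d, 100.0 * c2 / d, 100.0 * c3 / d)

    @property
    def genotyped_markers(self) -> int:
        return self.designed_markers - self.not_assayable

    @property
    def amplified_markers(self) -> int:
        return (self.genotyped_markers - self.failed_amplification
                - self.low_success_rate)

    @property
    def amplification_success_pct(self) -> float:
        return 100.0 * self.amplified_markers / self.designed_markers

    @property
    def failed_amplification_pct(self) -> float:
        return 100.0 * self.failed_amplification / self.designed_markers

    @property
    def low_success_pct(self) -> float:
        return 100.0 * self.low_success_rate / self.designed_markers

    @property
    def polymorphic_of_amplified_pct(self) -> float:
        return 100.0 * self.polymorphic / (self.polymorphic + self.monomorphic)


DAPHNIA_EST_FUNNEL = FunnelCounts()
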