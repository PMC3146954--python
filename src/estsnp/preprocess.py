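"""Read trimming and default-quality assignment.

ESTs enter the pipeline as single-pass cDNA reads with per-base Phred scores.
Before assembly they are cleaned: adapter remnants from library construction
are masked and removed, terminal polyA/polyT runs are stripped, low-complexity
reads are discarded, and anything shorter than a minimum length after trimming
is dropped.  Reads obtained without chromatogram-derived qualities (e.g. public
database ESTs) get a uniform imputed Phred score so that quality-aware stages
downstream can treat all reads alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "QualityRead",
    "TrimConfig",
    "MalformedReadError",
    "trim_reads",
    "assign_default_quality",
]

_DNA_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtn", "TGCANYRSWMKtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware for common codes)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


class MalformedReadError(ValueError):
    """Raised when a read's bases and qualities disagree in length."""


@dataclass
class QualityRead:
    """One EST read: bases plus per-base Phred scores and a library tag.

    ``quals_imputed`` marks reads whose qualities were assigned uniformly
    rather than derived from base calling.
    """

    read_id: str
    bases: str
    quals: list[int]
    library_tag: str = ""
    quals_imputed: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise MalformedReadError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class TrimConfig:
    """Trimming thresholds.

    min_length: reads shorter than this after trimming are dropped (bp).
    polya_min_run: minimum number of A (or T) in a terminal homopolymer-like
        run for it to be treated as a polyA/polyT tail.
    adapter_sequences: adapter/vector remnants searched with exact and
        single-mismatch matching.
    low_complexity_window / low_complexity_max_distinct: a read is discarded
        when any window of the given width contains at most this many distinct
        bases.
    default_quality: Phred score imputed onto quality-less reads.
    """

    min_length: int = 50
    polya_min_run: int = 10
    adapter_sequences: tuple[str, ...] = ()
    low_complexity_window: int = 30
    low_complexity_max_distinct: int = 2
    default_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.default_quality <= 93:
            raise ValueError("default_quality must be in [0, 93]")


@dataclass
class TrimReport:
    """Per-read disposition after trimming."""

    dispositions: dict[str, str] = field(default_factory=dict)

    def count(self, disposition: str) -> int:
        return sum(1 for d in self.dispositions.values() if d == disposition)


def _find_adapter(bases: str, adapter: str, max_mismatch: int = 1) -> int:
    """Leftmost start of ``adapter`` in ``bases`` allowing <= max_mismatch
    substitutions, or -1."""
    la, lb = len(adapter), len(bases)
    if la == 0 or la > lb:
        return -1
    for start in range(lb - la + 1):
        mism = 0
        for i in range(la):
            if bases[start + i] != adapter[i]:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return start
    return -1


def _strip_adapters(bases: str, quals: list[int], adapters: tuple[str, ...]) -> tuple[str, list[int]]:
    """Mask adapter hits and remove them together with the read end they sit in.

    A hit whose midpoint falls in the 5' half removes everything up to the hit
    end; a 3'-half hit removes from the hit start onward.  Repeats until no
    adapter remains (multiple remnants from concatenated cloning artefacts).
    """
    changed = True
    while changed and bases:
        changed = False
        for adapter in adapters:
            for probe in (adapter, revcomp(adapter)):
                pos = _find_adapter(bases, probe)
                if pos < 0:
                    continue
                mid = pos + len(probe) / 2
                if mid <= len(bases) / 2:
                    bases, quals = bases[pos + len(probe):], quals[pos + len(probe):]
                else:
                    bases, quals = bases[:pos], quals[:pos]
                changed = True
                break
            if changed:
                break
    return bases, quals


def _poly_tail_length(bases: str, letter: str, min_run: int,
                      max_impurities: int = 1) -> int:
    """Length of the longest suffix dominated by ``letter``.

    The suffix must begin with the letter, contain at least ``min_run``
    copies of it and at most ``max_impurities`` other bases (tolerating an
    isolated base-calling error inside a tail).  Returns 0 if no suffix
    qualifies.  Prefix scanning is done by the caller on the reversed string.
    """
    best = 0
    hits = 0
    n = len(bases)
    for i in range(1, n + 1):
        inner_is_letter = bases[n - i] == letter
        if inner_is_letter:
            hits += 1
        elif i - hits > max_impurities:
            break
        if inner_is_letter and hits >= min_run:
            best = i
    return best


def _strip_poly_tails(bases: str, quals: list[int], min_run: int) -> tuple[str, list[int]]:
    """Remove terminal polyA/polyT runs from both ends, to a fixed point."""
    changed = True
    while changed and bases:
        changed = False
        # trailing tail (polyA on mRNA-sense reads, polyT symmetrically)
        cut = max(_poly_tail_length(bases, "A", min_run),
                  _poly_tail_length(bases, "T", min_run))
        if cut:
            keep = len(bases) - cut
            bases, quals = bases[:keep], quals[:keep]
            changed = True
        # leading tail (polyT on reverse-complemented reads)
        rev = bases[::-1]
        cut = max(_poly_tail_length(rev, "T", min_run),
                  _poly_tail_length(rev, "A", min_run))
        if cut:
            bases, quals = bases[cut:], quals[cut:]
            changed = True
    return bases, quals


def _is_low_complexity(bases: str, window: int, max_distinct: int) -> bool:
    if len(bases) < window:
        return len(set(bases)) <= max_distinct if bases else False
    for start in range(len(bases) - window + 1):
        if len(set(bases[start : start + window])) <= max_distinct:
            return True
    return False


def trim_read(read: QualityRead, cfg: TrimConfig) -> tuple[QualityRead | None, str]:
    """Trim a single read; returns (trimmed read or None, disposition)."""
    if len(read.bases) != len(read.quals):  # defensive; dataclass validates too
        raise MalformedReadError(f"read {read.read_id!r}: length mismatch")
    bases, quals = _strip_adapters(read.bases, list(read.quals), cfg.adapter_sequences)
    bases, quals = _strip_poly_tails(bases, quals, cfg.polya_min_run)
    if _is_low_complexity(bases, cfg.low_complexity_window, cfg.low_complexity_max_distinct):
        return None, "dropped:low_complexity"
    if len(bases) < cfg.min_length:
        return None, "dropped:short"
    return replace(read, bases=bases, quals=quals), "kept"


def trim_reads(reads: list[QualityRead], cfg: TrimConfig) -> tuple[list[QualityRead], TrimReport]:
    """Apply the trimming cascade to every read.

    Order: adapter masking/removal, terminal polyA/polyT stripping,
    low-complexity screen, minimum-length screen.  Trimming is idempotent.
    """
    retained: list[QualityRead] = []
    report = TrimReport()
    for read in reads:
        trimmed, disposition = trim_read(read, cfg)
        report.dispositions[read.read_id] = disposition
        if trimmed is not None:
            retained.append(trimmed)
    return retained, report


def assign_default_quality(reads: list[QualityRead], q: int = 20) -> list[QualityRead]:
    """Give every base of every read the uniform Phred score ``q``.

    Used for reads whose chromatograms (and hence real qualities) are not
    available; the imputation is flagged on each read.
    """
    if not 0 <= q <= 93:
        raise ValueError("quality must be in [0, 93]")
    return [
        replace(read, quals=[q] * len(read.bases), quals_imputed=True)
        for read in reads
    ]
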