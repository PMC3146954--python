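"""Shared fixtures and contig-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from estsnp.assemble import AlignedRead, Contig, call_consensus
from estsnp.preprocess import QualityRead


def make_contig(rows, contig_id="c1") -> Contig:
    """Build a contig from (read_id, start_col, aligned_seq, quals) tuples.

    ``quals`` may be a single int (applied to every non-gap base) or a list
    matching the non-gap characters in order.
    """
    aligned = []
    for read_id, start, seq, quals in rows:
        if isinstance(quals, int):
            qlist = [None if ch == "-" else quals for ch in seq]
        else:
            it = iter(quals)
            qlist = [None if ch == "-" else next(it) for ch in seq]
        aligned.append(AlignedRead(read_id, "+", start, seq, qlist))
    contig = Contig(contig_id, aligned)
    call_consensus(contig)
    return contig


def read(read_id: str, bases: str, q: int = 30) -> QualityRead:
    return QualityRead(read_id, bases, [q] * len(bases))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_zero_error_library():
    """60-gene error-free library shared by the recovery tests."""
    from estsnp.synthgen import PhredProfile, generate_est_library

    return generate_est_library(60, 8.0, 0.004, PhredProfile(93, 93), seed=42)
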