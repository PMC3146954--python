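"""Per-locus, per-population summary statistics.

For every population x locus cell: allele frequency, observed heterozygosity
Ho, unbiased expected heterozygosity He = 2p(1-p) * 2n/(2n-1), and the
Hardy-Weinberg exact P-value.  The overall minor-allele frequency pools all
called genotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .hwe import hwe_exact_p

__all__ = ["locus_statistics"]


def locus_statistics(g: GenotypeMatrix) -> pd.DataFrame:
    """Tidy frame: one row per (locus, population) plus an 'overall' row per
    locus carrying the pooled minor-allele frequency."""
    rows = []
    for j, locus in enumerate(g.loci):
        col = g.dosages[:, j]
        pooled = col[~np.isnan(col)]
        overall_p = pooled.sum() / (2 * len(pooled)) if len(pooled) else np.nan
        maf = min(overall_p, 1 - overall_p) if np.isfinite(overall_p) else np.nan
        rows.append((locus, "overall", len(pooled), overall_p, maf,
                     np.nan, np.nan, np.nan))
        for pop in g.population_names:
            sub = col[g.population_mask(pop)]
            called = sub[~np.isnan(sub)]
            n = len(called)
            if n == 0:
                rows.append((locus, pop, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            p = called.sum() / (2 * n)
            ho = float((called == 1).mean())
            he = 2 * p * (1 - p) * (2 * n) / (2 * n - 1) if n > 1 else 0.0
            if p in (0.0, 1.0):
                ho, he, hwe_p = 0.0, 0.0, 1.0
            else:
                n_minor = int(min(called.sum(), 2 * n - called.sum()))
                hwe_p = hwe_exact_p(int((called == 1).sum()), n_minor, n)
            rows.append((locus, pop, n, p, min(p, 1 - p), ho, he, hwe_p))
    return pd.DataFrame(rows, columns=["locus", "population", "n_called",
                                       "allele_freq", "maf", "Ho", "He", "hwe_p"])
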