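"""Hardy–Weinberg exact test for biallelic genotypes.

The test conditions on the observed allele counts and fully enumerates the
possible heterozygote counts (which share the parity of the minor-allele
count); the P-value sums the probabilities of all configurations no more
likely than the observed one.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["hwe_exact_p"]


def _log_config_prob(n_het: int, n_minor: int, n_ind: int) -> float:
    """log P(heterozygote count | allele counts) under random union of
    gametes: n! / (n_AA! n_AB! n_BB!) * 2^n_AB * n_A! n_B! / (2n)!"""
    n_major = 2 * n_ind - n_minor
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = (n_major - n_het) // 2
    return (
        gammaln(n_ind + 1)
        - gammaln(n_hom_minor + 1) - gammaln(n_het + 1) - gammaln(n_hom_major + 1)
        + n_het * np.log(2)
        + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n_ind + 1)
    )


def hwe_exact_p(n_het: int, n_minor: int, n_ind: int) -> float:
    """Exact conditional Hardy–Weinberg P for an observed heterozygote count.

    ``n_minor`` is the minor-allele count (0..n_ind*2), ``n_ind`` the number
    of called individuals.  Monomorphic data return 1.
    """
    if n_ind <= 0:
        raise ValueError("need at least one called individual")
    n_minor = min(n_minor, 2 * n_ind - n_minor)
    if n_minor == 0:
        return 1.0
    if (n_het % 2) != (n_minor % 2) or n_het > n_minor or n_het < 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.array([_log_config_prob(int(h), n_minor, n_ind) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    # sum all configurations no more likely than observed (tiny tolerance for
    # float ties)
    return float(probs[probs <= obs * (1 + 1e-12)].sum())
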