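"""Weir–Cockerham F_ST (theta) for biallelic dosage data.

Per-locus variance components a (among populations), b (among individuals
within populations) and c (within individuals) follow the classic
unequal-sample-size, missing-aware estimator; theta = a / (a + b + c) per
locus, and the multilocus estimate sums components over loci before taking
the ratio.  Pairwise population theta comes with a permutation P-value
(individuals shuffled between the two populations, +1/(N+1) convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["FstResult", "variance_components", "wc_fst"]


@dataclass
class FstResult:
    per_locus: pd.Series                 # theta per locus (NaN where undefined)
    global_theta: float
    pairwise: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None
    n_permutations: int = 0


def population_summaries(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per population x locus: called sample size n, allele frequency p and
    observed heterozygote fraction h.  Arrays are (n_pops, n_loci); cells
    with no calls carry n = 0 and NaN p/h."""
    pops = g.population_names
    n = np.zeros((len(pops), g.n_loci))
    p = np.full((len(pops), g.n_loci), np.nan)
    h = np.full((len(pops), g.n_loci), np.nan)
    for i, pop in enumerate(pops):
        block = g.dosages[g.population_mask(pop)]
        called = ~np.isnan(block)
        n[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[i] = np.nansum(block, axis=0) / np.maximum(2 * n[i], 1)
            h[i] = np.nansum(block == 1, axis=0) / np.maximum(n[i], 1)
        p[i, n[i] == 0] = np.nan
        h[i, n[i] == 0] = np.nan
    return n, p, h


def variance_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham a, b, c per locus from per-population summaries.

    ``n`` (sample sizes), ``p`` (allele frequencies) and ``h`` (heterozygote
    fractions) are (n_pops, n_loci).  Loci with fewer than two populations
    sampled, or with a mean sample size of one, return NaN components.
    """
    n = np.asarray(n, float)
    p = np.where(n > 0, p, 0.0)
    h = np.where(n > 0, h, 0.0)
    r = (n > 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.sum(axis=0) / r
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _theta_from_summaries(n, p, h) -> tuple[np.ndarray, float]:
    a, b, c = variance_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(denom != 0, a / denom, np.nan)
    usable = np.isfinite(denom) & (denom != 0)
    total = denom[usable].sum()
    global_theta = float(a[usable].sum() / total) if usable.any() and total != 0 else float("nan")
    return per_locus, global_theta


def theta_from_summaries(n: np.ndarray, p: np.ndarray, h: np.ndarray
                         ) -> tuple[np.ndarray, float]:
    """(per-locus theta, multilocus theta) from population summaries.

    Loci monomorphic across the populations considered drop out of the
    multilocus sums (their components are all zero).
    """
    return _theta_from_summaries(n, p, h)


def wc_fst(g: GenotypeMatrix, pairwise: bool = True, n_permutations: int = 999,
           seed: int = 0) -> FstResult:
    """Per-locus, multilocus and (optionally) pairwise theta with permutation
    significance."""
    if len(g.population_names) < 2:
        raise ValueError("F_ST needs at least two populations")
    n, p, h = population_summaries(g)
    per_locus, global_theta = _theta_from_summaries(n, p, h)
    result = FstResult(pd.Series(per_locus, index=g.loci), global_theta)
    if not pairwise:
        return result
    pops = g.population_names
    theta_mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    p_mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            mask = g.population_mask(pa) | g.population_mask(pb)
            block = g.dosages[mask]
            labels = np.array([q for q in g.populations if q in (pa, pb)])
            obs = _pair_theta(block, labels == pa)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(labels == pa)
                if _pair_theta(block, perm) >= obs:
                    count += 1
            pval = (count + 1) / (n_permutations + 1)
            theta_mat.loc[pa, pb] = theta_mat.loc[pb, pa] = obs
            p_mat.loc[pa, pb] = p_mat.loc[pb, pa] = pval
    result.pairwise = theta_mat
    result.pairwise_p = p_mat
    result.n_permutations = n_permutations
    return result


def _pair_theta(block: np.ndarray, in_first: np.ndarray) -> float:
    n = np.zeros((2, block.shape[1]))
    p = np.zeros((2, block.shape[1]))
    h = np.zeros((2, block.shape[1]))
    for k, mask in enumerate((in_first, ~in_first)):
        sub = block[mask]
        called = ~np.isnan(sub)
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[k] = np.nansum(sub, axis=0) / np.maximum(2 * n[k], 1)
            h[k] = np.nansum(sub == 1, axis=0) / np.maximum(n[k], 1)
    _, global_theta = _theta_from_summaries(n, p, h)
    return global_theta
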