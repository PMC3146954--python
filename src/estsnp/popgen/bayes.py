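"""Simplified Bayesian outlier scan (logistic F decomposition).

An optional, deliberately reduced analogue of reversible-jump Bayesian
selection scans: per locus i and deme j the differentiation is decomposed as

    logit(F_ij) = alpha_i + beta_j

with a spike-and-slab prior on the locus effect alpha_i (point mass at zero
with prior probability 0.5, otherwise Normal(0, 3^2)) and Normal(-1, 1.8^2)
priors on the deme effects.  Deme allele counts are Beta-binomial given the
locus's ancestral frequency (Uniform prior) and F_ij.  A Metropolis sampler
alternates updates of the ancestral frequencies, the locus effects (with a
spike toggle move) and the deme effects.  Evidence for selection at locus i
is the Bayes factor of alpha_i != 0, i.e. its posterior inclusion odds
(prior odds are even); BF >= 3 is the conventional flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit

from .fst import population_summaries
from .genotypes import GenotypeMatrix

__all__ = ["BayesScanResult", "bayes_outlier_scan"]


@dataclass
class BayesScanResult:
    table: pd.DataFrame          # locus, posterior_selection, bayes_factor, flagged
    reliable: bool
    n_iterations: int


def _loglik(alt: np.ndarray, tot: np.ndarray, p: np.ndarray,
            f: np.ndarray) -> np.ndarray:
    """Per-locus Beta-binomial log-likelihood summed over demes.

    alt/tot: (demes, loci) allele counts; p: (loci,); f: (demes, loci).
    """
    f = np.clip(f, 1e-6, 1 - 1e-6)
    lam = (1 - f) / f
    a = np.maximum(p * lam, 1e-9)
    b = np.maximum((1 - p) * lam, 1e-9)
    return (betaln(alt + a, tot - alt + b) - betaln(a, b)).sum(axis=0)


def bayes_outlier_scan(g: GenotypeMatrix, n_iterations: int = 100_000,
                       burn_in: int = 50_000, thinning: int = 20,
                       spike_prob: float = 0.5, seed: int = 0,
                       bf_threshold: float = 3.0) -> BayesScanResult:
    """Spike-and-slab scan for locus-specific differentiation.

    ``spike_prob`` is the prior mass on alpha = 0; setting it to 1 forbids
    the selection model entirely (all Bayes factors zero).  A split-chain
    disagreement heuristic (inclusion frequencies differing by more than
    0.25 on average) marks the result unreliable.
    """
    n, p_obs, _ = population_summaries(g)
    tot = (2 * n)
    alt = np.where(n > 0, p_obs, 0.0) * tot
    d, m = tot.shape
    rng = np.random.default_rng(seed)

    p = np.clip(np.nansum(alt, axis=0) / np.maximum(tot.sum(axis=0), 1), 0.05, 0.95)
    alpha = np.zeros(m)
    include = np.zeros(m, dtype=bool)
    beta = np.full(d, -1.0)
    sigma_alpha, mu_beta, sigma_beta = 3.0, -1.0, 1.8

    def f_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return expit(a[None, :] + b[:, None])

    ll = _loglik(alt, tot, p, f_matrix(alpha, beta))
    keep_incl = []
    n_kept = 0
    for it in range(n_iterations):
        # ancestral frequencies (vectorized Metropolis, reflecting proposals)
        prop_p = np.abs(p + rng.normal(0, 0.05, size=m))
        prop_p = np.where(prop_p > 1, 2 - prop_p, prop_p)
        prop_p = np.clip(prop_p, 1e-4, 1 - 1e-4)
        ll_prop = _loglik(alt, tot, prop_p, f_matrix(alpha, beta))
        accept = np.log(rng.random(m)) < ll_prop - ll
        p = np.where(accept, prop_p, p)
        ll = np.where(accept, ll_prop, ll)

        # locus effects: toggle spike membership or perturb the slab value
        if spike_prob < 1.0:
            prop_include = include.copy()
            prop_alpha = alpha.copy()
            toggle = rng.random(m) < 0.5
            draw = rng.normal(0, sigma_alpha, size=m)
            walk = alpha + rng.normal(0, 0.4, size=m)
            prop_include[toggle] = ~include[toggle]
            prop_alpha = np.where(toggle, np.where(prop_include, draw, 0.0),
                                  np.where(include, walk, 0.0))
            ll_prop = _loglik(alt, tot, p, f_matrix(prop_alpha, beta))
            # prior ratio: spike vs slab mass; the slab proposal for toggles is
            # drawn from the prior so it cancels against the prior density
            log_prior = np.where(
                toggle,
                np.where(prop_include,
                         np.log((1 - spike_prob) / spike_prob),
                         np.log(spike_prob / (1 - spike_prob))),
                np.where(include,
                         -(prop_alpha ** 2 - alpha ** 2) / (2 * sigma_alpha ** 2),
                         0.0),
            )
            accept = np.log(rng.random(m)) < ll_prop - ll + log_prior
            alpha = np.where(accept, prop_alpha, alpha)
            include = np.where(accept, prop_include, include)
            ll = np.where(accept, ll_prop, ll)

        # deme effects, one at a time
        for j in range(d):
            prop_beta = beta.copy()
            prop_beta[j] += rng.normal(0, 0.2)
            ll_prop = _loglik(alt, tot, p, f_matrix(alpha, prop_beta))
            log_prior = (-(prop_beta[j] - mu_beta) ** 2
                         + (beta[j] - mu_beta) ** 2) / (2 * sigma_beta ** 2)
            if np.log(rng.random()) < ll_prop.sum() - ll.sum() + log_prior:
                beta = prop_beta
                ll = ll_prop

        if it >= burn_in and (it - burn_in) % thinning == 0:
            keep_incl.append(include.copy())
            n_kept += 1

    incl = np.array(keep_incl) if keep_incl else np.zeros((1, m), dtype=bool)
    post = incl.mean(axis=0)
    with np.errstate(divide="ignore"):
        bf = post / np.maximum(1 - post, 1e-12)
    half = len(incl) // 2
    reliable = True
    if half >= 10:
        disagreement = np.abs(incl[:half].mean(axis=0) - incl[half:].mean(axis=0))
        reliable = bool(disagreement.mean() <= 0.25)
    table = pd.DataFrame({
        "locus": g.loci,
        "posterior_selection": post,
        "bayes_factor": bf,
        "flagged": bf >= bf_threshold,
    })
    return BayesScanResult(table, reliable, n_iterations)
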