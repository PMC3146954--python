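"""Locus statistics, exact Hardy-Weinberg test, Weir-Cockerham theta."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from estsnp.popgen import (GenotypeMatrix, hwe_exact_p, locus_statistics,
                           wc_fst)
from estsnp.popgen.fst import population_summaries, variance_components


def matrix(dosages, pops, coords=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(dosages, [f"i{k}" for k in range(n)], list(pops),
                          [f"L{j}" for j in range(m)],
                          coords if coords is not None else pd.DataFrame())


def hwe_oracle(n_het, n_minor, n):
    """Exact-rational enumeration of the conditional HWE distribution."""
    n_major = 2 * n - n_minor
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = (n_major - h) // 2
        if hom_major < 0:
            continue
        weights[h] = (Fraction(2) ** h * comb(n, hom_minor)
                      * comb(n - hom_minor, h)
                      * comb(n - hom_minor - h, hom_major))
    total = sum(weights.values())
    obs = Fraction(weights[n_het], 1) / total
    return float(sum(Fraction(w, 1) / total for w in weights.values()
                     if Fraction(w, 1) / total <= obs))


def test_all_heterozygous_small_sample():
    g = matrix([[1]] * 5, ["p1"] * 5)
    stats = locus_statistics(g)
    row = stats[(stats.population == "p1")].iloc[0]
    assert row.Ho == 1.0
    assert row.hwe_p == pytest.approx(hwe_oracle(5, 5, 5), abs=1e-12)


def test_monomorphic_locus_degenerate_values():
    g = matrix([[0], [0], [0]], ["p1"] * 3)
    row = locus_statistics(g).query("population == 'p1'").iloc[0]
    assert (row.Ho, row.He, row.hwe_p) == (0.0, 0.0, 1.0)


def test_he_small_sample_correction():
    g = matrix([[0], [1], [2], [1]], ["p1"] * 4)
    row = locus_statistics(g).query("population == 'p1'").iloc[0]
    p = 4 / 8
    assert row.He == pytest.approx(2 * p * (1 - p) * 8 / 7)
    assert row.allele_freq == pytest.approx(0.5)


def test_hwe_matches_rational_oracle_to_2n_20():
    for n in range(1, 11):
        for n_minor in range(1, n + 1):
            for h in range(n_minor % 2, n_minor + 1, 2):
                assert hwe_exact_p(h, n_minor, n) == pytest.approx(
                    hwe_oracle(h, n_minor, n), abs=1e-12)


def test_theta_zero_for_identical_populations(rng):
    freqs = rng.uniform(0.2, 0.8, size=40)
    dosages = rng.binomial(2, freqs, size=(400, 40))
    g = matrix(dosages, ["a"] * 200 + ["b"] * 200)
    res = wc_fst(g, pairwise=False)
    assert abs(res.global_theta) < 0.01


def test_theta_one_for_fixed_alternate_demes():
    dosages = [[0] * 5] * 10 + [[2] * 5] * 10
    g = matrix(dosages, ["a"] * 10 + ["b"] * 10)
    res = wc_fst(g, pairwise=False)
    assert res.per_locus.to_numpy() == pytest.approx(np.ones(5))
    assert res.global_theta == pytest.approx(1.0)


def test_variance_components_match_literal_formula(rng):
    """Vectorized components equal a plain per-locus transcription of the
    1984 estimator written independently here."""
    dosages = rng.binomial(2, 0.4, size=(60, 8)).astype(float)
    dosages[rng.random(dosages.shape) < 0.05] = np.nan
    pops = ["a"] * 20 + ["b"] * 25 + ["c"] * 15
    g = matrix(dosages, pops)
    n, p, h = population_summaries(g)
    a_vec, b_vec, c_vec = variance_components(n, p, h)
    for j in range(g.n_loci):
        ns = [n[i, j] for i in range(3) if n[i, j] > 0]
        ps = [p[i, j] for i in range(3) if n[i, j] > 0]
        hs = [h[i, j] for i in range(3) if n[i, j] > 0]
        r = len(ns)
        nbar = sum(ns) / r
        nc = (r * nbar - sum(x * x for x in ns) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(ns, ps)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        assert a_vec[j] == pytest.approx(a, abs=1e-12)
        assert b_vec[j] == pytest.approx(b, abs=1e-12)
        assert c_vec[j] == pytest.approx(c, abs=1e-12)


def test_theta_invariant_to_allele_relabeling(rng):
    dosages = rng.binomial(2, rng.uniform(0.2, 0.8, 20), size=(80, 20)).astype(float)
    pops = ["a"] * 40 + ["b"] * 40
    res1 = wc_fst(matrix(dosages, pops), pairwise=False)
    res2 = wc_fst(matrix(2 - dosages, pops), pairwise=False)
    np.testing.assert_allclose(res1.per_locus, res2.per_locus, atol=1e-12)
    assert res1.global_theta == pytest.approx(res2.global_theta, abs=1e-12)


def test_pairwise_matrix_symmetric_with_permutation_p(rng):
    from estsnp.synthgen import generate_island_genotypes
    g, _ = generate_island_genotypes(3, 15, 20, 0.15, seed=3)
    res = wc_fst(g, pairwise=True, n_permutations=99, seed=1)
    mat = res.pairwise.to_numpy()
    assert np.allclose(mat, mat.T, equal_nan=True)
    assert np.isnan(np.diag(mat)).all()
    off = res.pairwise_p.to_numpy()[~np.isnan(res.pairwise_p.to_numpy())]
    assert ((off > 0) & (off <= 1)).all()


def test_single_population_rejected():
    g = matrix([[0], [1]], ["a", "a"])
    with pytest.raises(ValueError):
        wc_fst(g)


def test_large_sample_hw_proportions_limit(rng):
    """p = 0.5 with genotypes in exact HW proportions: Ho and He both
    approach 0.5 and the exact test does not reject."""
    dosages = rng.binomial(2, 0.5, size=(5000, 1)).astype(float)
    g = matrix(dosages, ["p1"] * 5000)
    row = locus_statistics(g).query("population == 'p1'").iloc[0]
    assert abs(row.Ho - 0.5) < 0.03
    assert abs(row.He - 0.5) < 0.03
    assert row.hwe_p > 0.01
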