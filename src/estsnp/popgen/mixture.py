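"""Non-spatial Bayesian mixture clustering of individuals.

Model: a K-component mixture with symmetric Dirichlet(1) weights and, within
each cluster, an independent Beta(1,1) allele-frequency prior per biallelic
locus, both integrated out analytically.  A partition's score is the
collapsed log marginal

    log P(data, labels | K) = log Gamma(K) - log Gamma(n + K)
                              + sum_k log Gamma(n_k + 1)
                              + sum_k sum_l log B(c1_kl + 1, c0_kl + 1)

(up to constants), where n_k are cluster sizes and c1/c0 allele counts in
cluster k at locus l.  The allocation term penalises gratuitous splitting,
so sampling noise cannot buy extra clusters.  For each K a stochastic greedy
search -- random initial labels, then sweeps moving every individual to its
best cluster until no move helps -- is restarted from several random seeds;
the selected K maximizes the best score found (smallest K on ties, so empty
clusters never inflate K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

from .genotypes import GenotypeMatrix

__all__ = ["ClusterAssignment", "mixture_clustering", "partition_score"]


@dataclass
class ClusterAssignment:
    selected_k: int
    labels: np.ndarray               # best partition at selected_k, values 0..K-1
    scores: dict[int, float]         # per K: best log marginal likelihood
    labels_by_k: dict[int, np.ndarray]


def _allele_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    d = g.dosages
    x1 = np.where(np.isnan(d), 0.0, d)
    x0 = np.where(np.isnan(d), 0.0, 2.0 - d)
    return x1, x0


def partition_score(g: GenotypeMatrix, labels: np.ndarray,
                    k: int | None = None) -> float:
    """Collapsed log marginal of a labelled partition under the K-component
    mixture (Dirichlet(1) weights, Beta(1,1) allele frequencies)."""
    labels = np.asarray(labels)
    if k is None:
        k = int(labels.max()) + 1
    x1, x0 = _allele_counts(g)
    n = len(labels)
    score = float(gammaln(k) - gammaln(n + k))
    for kk in np.unique(labels):
        mask = labels == kk
        c1 = x1[mask].sum(axis=0)
        c0 = x0[mask].sum(axis=0)
        score += float(gammaln(mask.sum() + 1))
        score += float(betaln(c1 + 1, c0 + 1).sum())
    return score


class _GreedyState:
    """Cluster allele counts plus cached per-cluster log-predictives for the
    three dosage values (and a zero slot for missing calls)."""

    def __init__(self, x1: np.ndarray, x0: np.ndarray, labels: np.ndarray, k: int):
        self.x1, self.x0 = x1, x0
        self.k = k
        n_loci = x1.shape[1]
        self.c1 = np.zeros((k, n_loci))
        self.c0 = np.zeros((k, n_loci))
        self.sizes = np.zeros(k)
        for kk in range(k):
            mask = labels == kk
            self.c1[kk] = x1[mask].sum(axis=0)
            self.c0[kk] = x0[mask].sum(axis=0)
            self.sizes[kk] = mask.sum()
        self.logpred = np.zeros((k, n_loci, 4))
        for kk in range(k):
            self._refresh(kk)
        # dosage codes per individual per locus: 0,1,2 observed; 3 missing
        self.codes = np.where(x1 + x0 == 0, 3, x1).astype(int)
        self.cols = np.arange(n_loci)

    def _refresh(self, kk: int) -> None:
        c1, c0 = self.c1[kk], self.c0[kk]
        t = c1 + c0
        denom = np.log((t + 2) * (t + 3))
        self.logpred[kk, :, 0] = np.log((c0 + 1) * (c0 + 2)) - denom
        self.logpred[kk, :, 1] = np.log(2 * (c1 + 1) * (c0 + 1)) - denom
        self.logpred[kk, :, 2] = np.log((c1 + 1) * (c1 + 2)) - denom
        self.logpred[kk, :, 3] = 0.0

    def remove(self, i: int, kk: int) -> None:
        self.c1[kk] -= self.x1[i]
        self.c0[kk] -= self.x0[i]
        self.sizes[kk] -= 1
        self._refresh(kk)

    def add(self, i: int, kk: int) -> None:
        self.c1[kk] += self.x1[i]
        self.c0[kk] += self.x0[i]
        self.sizes[kk] += 1
        self._refresh(kk)

    def best_cluster(self, i: int) -> int:
        # genotype predictive plus the collapsed allocation term log(n_k + 1)
        gains = (self.logpred[:, self.cols, self.codes[i]].sum(axis=1)
                 + np.log(self.sizes + 1))
        return int(np.argmax(gains))


def _greedy_search(x1: np.ndarray, x0: np.ndarray, k: int,
                   rng: np.random.Generator, max_sweeps: int = 60) -> np.ndarray:
    n = x1.shape[0]
    labels = rng.integers(0, k, size=n)
    state = _GreedyState(x1, x0, labels, k)
    for _ in range(max_sweeps):
        moved = 0
        for i in rng.permutation(n):
            old = labels[i]
            state.remove(i, old)
            new = state.best_cluster(i)
            state.add(i, new)
            if new != old:
                labels[i] = new
                moved += 1
        if moved == 0:
            break
    return labels


def mixture_clustering(g: GenotypeMatrix, k_range: range | list = range(2, 13),
                       n_restarts: int = 20, seed: int = 0) -> ClusterAssignment:
    """Search partitions for each K and select the best-scoring K.

    Deterministic given the seed.  The number of occupied clusters in the
    returned labels can be below K (empty clusters carry no likelihood)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > g.n_individuals:
        raise ValueError("K range must lie within [1, number of individuals]")
    x1, x0 = _allele_counts(g)
    rng = np.random.default_rng(seed)
    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        best_score, best_labels = -np.inf, None
        for _ in range(n_restarts):
            labels = _greedy_search(x1, x0, k, rng)
            score = partition_score(g, labels, k)
            if score > best_score:
                best_score, best_labels = score, labels
        scores[k] = best_score
        labels_by_k[k] = best_labels
    # effective K: occupied clusters of the chosen partition; ties in score
    # resolve to the smallest K
    selected = min(ks, key=lambda k: (-round(scores[k], 6), k))
    labels = labels_by_k[selected]
    return ClusterAssignment(
        selected_k=int(len(np.unique(labels))),
        labels=labels,
        scores=scores,
        labels_by_k=labels_by_k,
    )
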