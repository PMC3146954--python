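"""F_ST-versus-heterozygosity outlier scan with a forced mean F_ST.

The neutral envelope is built by simulation: Balding–Nichols deme frequencies
around uniform ancestral frequencies, matched to the observed deme count and
sample sizes, with the simulation F calibrated by bisection so that the mean
simulated multilocus theta reproduces the observed one ("forced mean F_ST").
Simulated loci are binned by expected heterozygosity (equal occupancy) and
per-bin theta quantiles form the envelope; observed loci falling below or
above their bin's quantiles are flagged as candidate targets of selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst import theta_from_summaries, population_summaries
from .genotypes import GenotypeMatrix

__all__ = ["OutlierReport", "CalibrationError", "outlier_scan"]


class CalibrationError(RuntimeError):
    """Bisection could not force the simulated mean theta onto the target."""


@dataclass
class OutlierReport:
    table: pd.DataFrame          # locus, he, theta, lower, upper, classification
    f_sim: float                 # calibrated simulation F
    observed_global_theta: float
    n_simulated: int

    @property
    def neutral_loci(self) -> list[str]:
        return self.table.loc[self.table.classification == "neutral", "locus"].tolist()

    def flagged(self, kind: str) -> list[str]:
        return self.table.loc[self.table.classification == kind, "locus"].tolist()


def _simulate_summaries(f: float, deme_sizes: np.ndarray, n_loci: int,
                        rng: np.random.Generator,
                        ancestral_range: tuple[float, float] = (0.02, 0.98)):
    """Neutral Balding–Nichols loci -> per-deme (n, p, h) summaries plus the
    pooled-sample expected heterozygosity axis."""
    d = len(deme_sizes)
    p_anc = rng.uniform(*ancestral_range, size=n_loci)
    lam = (1 - f) / max(f, 1e-9)
    freqs = rng.beta(np.maximum(p_anc * lam, 1e-9),
                     np.maximum((1 - p_anc) * lam, 1e-9), size=(d, n_loci))
    sizes = np.asarray(deme_sizes)[:, None]
    # genotype counts per deme/locus: hom-alt then het, conditionally binomial
    hom_alt = rng.binomial(sizes, freqs ** 2)
    rest = sizes - hom_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p_het = np.where(freqs < 1, 2 * freqs * (1 - freqs) / (1 - freqs ** 2), 0.0)
    het = rng.binomial(rest, np.clip(p_het, 0, 1))
    n = np.broadcast_to(sizes, freqs.shape).astype(float)
    p = (2 * hom_alt + het) / (2 * n)
    h = het / n
    pooled = (n * p).sum(axis=0) / n.sum(axis=0)
    he = 2 * pooled * (1 - pooled)
    return n, p, h, he


def _mean_theta(f: float, deme_sizes: np.ndarray, n_loci: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    n, p, h, _ = _simulate_summaries(f, deme_sizes, n_loci, rng)
    _, global_theta = theta_from_summaries(n, p, h)
    return global_theta


def _calibrate(target: float, deme_sizes: np.ndarray, seed: int,
               tol: float = 0.005, n_loci: int = 3000, max_iter: int = 40) -> float:
    """Bisect the simulation F so the simulated mean theta hits ``target``.

    Common random numbers (the same seed at every evaluation) make the
    simulated mean monotone in F, so bisection is well posed.
    """
    lo, hi = 1e-4, 0.95
    t_lo = _mean_theta(lo, deme_sizes, n_loci, seed)
    t_hi = _mean_theta(hi, deme_sizes, n_loci, seed)
    if not t_lo <= target <= t_hi:
        raise CalibrationError(
            f"target theta {target:.4f} outside achievable range "
            f"[{t_lo:.4f}, {t_hi:.4f}]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        t_mid = _mean_theta(mid, deme_sizes, n_loci, seed)
        if abs(t_mid - target) <= tol:
            return mid
        if t_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def outlier_scan(g: GenotypeMatrix, n_sim: int = 10_000, n_bins: int = 20,
                 envelope: tuple[float, float] = (0.025, 0.975),
                 seed: int = 0) -> OutlierReport:
    """Classify every locus against the simulated neutral envelope.

    Loci with zero pooled heterozygosity cannot be placed on the He axis and
    are reported neutral-by-convention with an ``unclassifiable`` flag.
    """
    n, p, h = population_summaries(g)
    per_locus, global_theta = theta_from_summaries(n, p, h)
    if not np.isfinite(global_theta):
        raise CalibrationError("observed multilocus theta undefined "
                               "(no polymorphic locus)")
    deme_sizes = np.round(np.nanmean(np.where(n > 0, n, np.nan), axis=1)).astype(int)
    deme_sizes = np.maximum(deme_sizes, 2)
    f_sim = _calibrate(global_theta, deme_sizes, seed)

    rng = np.random.default_rng(seed + 1)
    ns, ps, hs, he_sim = _simulate_summaries(f_sim, deme_sizes, n_sim, rng)
    theta_sim, _ = theta_from_summaries(ns, ps, hs)
    keep = np.isfinite(theta_sim) & (he_sim > 0)
    theta_sim, he_sim = theta_sim[keep], he_sim[keep]

    edges = np.quantile(he_sim, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = 0.0, 1.0
    lower = np.empty(n_bins)
    upper = np.empty(n_bins)
    for b in range(n_bins):
        mask = (he_sim >= edges[b]) & (he_sim <= edges[b + 1])
        vals = theta_sim[mask]
        lower[b] = np.quantile(vals, envelope[0])
        upper[b] = np.quantile(vals, envelope[1])

    with np.errstate(invalid="ignore"):
        pooled = np.nansum(n * np.where(n > 0, p, 0.0), axis=0) / n.sum(axis=0)
    he_obs = 2 * pooled * (1 - pooled)
    rows = []
    for j, locus in enumerate(g.loci):
        he_j, th_j = he_obs[j], per_locus[j]
        if not np.isfinite(th_j) or he_j <= 0:
            rows.append((locus, he_j, th_j, np.nan, np.nan, "neutral", True))
            continue
        b = int(np.clip(np.searchsorted(edges, he_j, side="right") - 1, 0, n_bins - 1))
        if th_j < lower[b]:
            cls = "low_outlier"
        elif th_j > upper[b]:
            cls = "high_outlier"
        else:
            cls = "neutral"
        rows.append((locus, he_j, th_j, lower[b], upper[b], cls, False))
    table = pd.DataFrame(rows, columns=["locus", "he", "theta", "lower",
                                        "upper", "classification",
                                        "unclassifiable"])
    return OutlierReport(table, f_sim, global_theta, int(keep.sum()))
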