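"""Null model, clustering p-values, and decoy-based FDR.

The null hypothesis for a motif annotating k proteins is that those k
proteins are a random draw from the network, with each protein's selection
probability proportional to the length of its 5' UTR (longer UTRs contain
more motif matches by chance, so a uniform null would overstate clustering).
S_k denotes the TPPD of such a random k-set.  The p-value of a motif m is
Pr[S_k <= TPPD(V_m)], a left-tail probability: unusually *small* TPPD means
unusually tight clustering.

Two regimes approximate the distribution of S_k:

* small k (<= ``k_switch``, default 300): an empirical Monte Carlo sample
  (default one million draws, giving p-value resolution ~1e-6); when the
  observed value undercuts every sample, fall back to a normal tail fitted
  on the same draws, capped at 1/n_samples to keep p monotone in the
  statistic;
* large k (``k_switch`` < k <= ``k_max``, default 1500): a normal
  approximation N(mu_k, sigma_k^2) with moments estimated from a smaller
  Monte Carlo sample (default 1e5 draws).

Motifs annotating more than ``k_max`` proteins are not assessed.

Multiple testing is handled not by a Bonferroni-style correction (the
motifs are heavily dependent variants of one another) but by an empirical
FDR: the entire pipeline is re-run on locally scrambled decoy sequences and
FDR(p) = N(p) / M(p), the ratio of decoy to real motifs at threshold p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import tppd_batch
from .network import DistanceMatrix

__all__ = [
    "weighted_sample",
    "monte_carlo_null",
    "fit_normal_null",
    "NullModel",
    "MotifNotAssessed",
    "clustering_pvalue",
    "FDRTable",
    "compute_fdr",
]


class MotifNotAssessed(Exception):
    """Raised when a set size exceeds the assessable range (k > k_max)."""


def _positive_weight_indices(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=np.float64)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    pos = np.flatnonzero(weights > 0)
    if len(pos) == 0:
        raise ValueError("no protein has positive sampling weight")
    return pos


def _sample_index_batch(rng, weights: np.ndarray, n_samples: int, k: int) -> np.ndarray:
    """(n_samples, k) index sets drawn without replacement, probability
    proportional to weight.

    Uses exponential sort keys (Efraimidis-Spirakis): taking the k smallest
    of Exp(1)/w_i is distributionally identical to sequentially drawing
    proportional-to-weight without replacement.
    """
    pos = _positive_weight_indices(weights)
    if k > len(pos):
        raise ValueError(f"cannot sample {k} proteins from {len(pos)} with positive weight")
    keys = rng.standard_exponential((n_samples, len(pos))) / weights[pos]
    chosen = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < len(pos) else (
        np.broadcast_to(np.arange(len(pos)), (n_samples, len(pos))).copy()
    )
    return pos[chosen]


def weighted_sample(weights: Mapping[str, float], k: int, seed: int = 0) -> Tuple[str, ...]:
    """Sample ``k`` distinct proteins, each draw proportional to its weight
    among the remaining proteins; deterministic given ``seed``.

    ``weights`` maps protein identifier to a positive weight (UTR length).
    Returns the sampled identifiers sorted for determinism.
    """
    proteins = sorted(weights)
    w = np.array([weights[p] for p in proteins], dtype=np.float64)
    if k > len(proteins):
        raise ValueError(f"k={k} exceeds population size {len(proteins)}")
    rng = np.random.default_rng(seed)
    idx = _sample_index_batch(rng, w, 1, k)[0]
    return tuple(sorted(proteins[i] for i in idx))


def monte_carlo_null(
    dist: DistanceMatrix,
    weights: np.ndarray,
    k: int,
    n_samples: int = 10**6,
    top_fraction: float = 0.1,
    seed: int = 0,
    chunk: int = 4096,
) -> np.ndarray:
    """Empirical sample of S_k: TPPD of ``n_samples`` weighted random k-sets.

    ``weights`` is aligned with ``dist.nodes``; zero-weight nodes (e.g. no
    UTR available) are never drawn.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_samples, dtype=np.int64)
    for lo in range(0, n_samples, chunk):
        c = min(chunk, n_samples - lo)
        idx = _sample_index_batch(rng, weights, c, k)
        out[lo : lo + c] = tppd_batch(dist, idx, top_fraction, chunk=chunk)
    return out


def fit_normal_null(
    dist: DistanceMatrix,
    weights: np.ndarray,
    k: int,
    n_samples: int = 10**5,
    top_fraction: float = 0.1,
    seed: int = 0,
) -> Tuple[float, float]:
    """(mu_k, sigma_k) of S_k estimated by Monte Carlo for the large-k regime."""
    samples = monte_carlo_null(dist, weights, k, n_samples, top_fraction, seed)
    mu = float(samples.mean())
    sigma = float(samples.std(ddof=1))
    if sigma == 0:
        raise ValueError(
            f"degenerate null at k={k}: all sampled TPPD values equal {mu:g}"
        )
    return mu, sigma


@dataclass
class NullModel:
    """Lazily built, per-k cached null distribution of S_k.

    For k <= ``k_switch`` the empirical sample vector is stored; above it
    only the fitted (mu_k, sigma_k).  The per-k random stream is derived
    from (seed, k), so results do not depend on the order in which k values
    are requested, and motifs of equal k share one sample set.
    """

    dist: DistanceMatrix
    weights: np.ndarray
    top_fraction: float = 0.1
    k_switch: int = 300
    k_max: int = 1500
    mc_samples_small: int = 10**6
    mc_samples_large: int = 10**5
    seed: int = 0
    _empirical: Dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _normal: Dict[int, Tuple[float, float]] = field(default_factory=dict, repr=False)

    def _rng_seed(self, k: int):
        return np.random.SeedSequence(self.seed, spawn_key=(k,))

    def regime(self, k: int) -> str:
        if k > self.k_max:
            return "not-assessed"
        return "empirical" if k <= self.k_switch else "normal"

    def samples_for(self, k: int) -> np.ndarray:
        if k > self.k_switch:
            raise ValueError(f"k={k} is in the normal regime (k_switch={self.k_switch})")
        if k not in self._empirical:
            self._empirical[k] = monte_carlo_null(
                self.dist,
                self.weights,
                k,
                self.mc_samples_small,
                self.top_fraction,
                self._rng_seed(k),
            )
        return self._empirical[k]

    def normal_params(self, k: int) -> Tuple[float, float]:
        """(mu_k, sigma_k); sigma may be 0 when the null is degenerate
        (e.g. k equals the whole sampleable population)."""
        if k not in self._normal:
            if k <= self.k_switch:
                samples = self.samples_for(k)
            else:
                samples = monte_carlo_null(
                    self.dist,
                    self.weights,
                    k,
                    self.mc_samples_large,
                    self.top_fraction,
                    self._rng_seed(k),
                )
            self._normal[k] = (float(samples.mean()), float(samples.std(ddof=1)))
        return self._normal[k]

    def pvalue(self, observed: float, k: int) -> float:
        """Pr[S_k <= observed]; ties count into the left tail."""
        if k > self.k_max:
            raise MotifNotAssessed(
                f"motif annotates {k} proteins, above the assessable limit {self.k_max}"
            )
        if k <= self.k_switch:
            samples = self.samples_for(k)
            n = len(samples)
            count = int((samples <= observed).sum())
            if count > 0:
                return count / n
            # Below every Monte Carlo draw: normal tail fitted on the same
            # draws, capped at 1/n so p stays monotone in the statistic.
            mu, sigma = self.normal_params(k)
            if sigma == 0:
                return 1.0 / n
            p = float(stats.norm.cdf(observed, loc=mu, scale=sigma))
            return float(np.clip(min(p, 1.0 / n), 1e-300, 1.0))
        mu, sigma = self.normal_params(k)
        if sigma == 0:
            # Degenerate null: a single achievable value (e.g. the set is
            # the entire population), so any observation at or above it has
            # the full left tail.
            return 1.0 if observed >= mu else 1e-300
        p = float(stats.norm.cdf(observed, loc=mu, scale=sigma))
        return float(np.clip(p, 1e-300, 1.0))

    # -- persistence -------------------------------------------------------

    def cache_frame(self) -> pd.DataFrame:
        """Fitted normal parameters per k, for TSV persistence."""
        rows = [
            {"k": k, "mu": mu, "sigma": sigma}
            for k, (mu, sigma) in sorted(self._normal.items())
        ]
        return pd.DataFrame(rows, columns=["k", "mu", "sigma"])


def clustering_pvalue(observed: float, null: NullModel, k: int) -> float:
    """Left-tail clustering p-value Pr[S_k <= observed] (see NullModel)."""
    return null.pvalue(observed, k)


@dataclass(frozen=True)
class FDRTable:
    """FDR(p) = N(p)/M(p): decoy vs real motif counts below each threshold."""

    thresholds: np.ndarray
    m_real: np.ndarray
    n_decoy: np.ndarray
    fdr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pvalue_threshold": self.thresholds,
                "n_real": self.m_real,
                "n_decoy": self.n_decoy,
                "fdr": self.fdr,
            }
        )

    def fdr_at(self, p: float) -> float:
        """FDR at the largest tabulated threshold <= p (1.0 if none)."""
        i = np.searchsorted(self.thresholds, p, side="right") - 1
        return float(self.fdr[i]) if i >= 0 else 1.0


def compute_fdr(
    real_pvalues: Sequence[float],
    decoy_pvalues: Sequence[float],
    thresholds: Optional[Sequence[float]] = None,
) -> FDRTable:
    """Empirical FDR from a decoy run of the identical pipeline.

    M(p) counts real motifs with p-value <= p, N(p) decoy motifs; FDR(p) =
    N(p)/M(p), capped at 1, and reported as 1 where M(p) = 0 (undefined).
    Thresholds default to the observed real p-values (step function).
    """
    real = np.sort(np.asarray(real_pvalues, dtype=np.float64))
    decoy = np.sort(np.asarray(decoy_pvalues, dtype=np.float64))
    if thresholds is None:
        thresholds = np.unique(real)
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))
    m = np.searchsorted(real, thresholds, side="right").astype(np.int64)
    n = np.searchsorted(decoy, thresholds, side="right").astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(m > 0, np.minimum(n / np.maximum(m, 1), 1.0), 1.0)
    return FDRTable(thresholds=thresholds, m_real=m, n_decoy=n, fdr=fdr)
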