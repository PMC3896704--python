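"""Candidate-gene-set enrichment via the hypergeometric upper tail.

Given a universe of N captured genes containing K candidate-list genes, and
n genes hit by surviving variants of which k are candidates, the one-sided
enrichment p-value is P(X >= k) for X ~ Hypergeometric(N, K, n), and the
fold enrichment is (k/K)/(n/N).  A permutation null is provided as an
independent check of the analytic tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "enrichment",
    "permutation_null",
]


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), summed in log space for stability.

    ``K`` candidate genes in a universe of ``N``; ``n`` draws; ``k``
    observed candidates among the draws.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid counts K={K}, n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside attainable range [{lo}, {hi}]")
    j = np.arange(k, hi + 1)
    log_terms = (
        _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    )
    m = log_terms.max()
    return float(min(1.0, np.exp(m) * np.exp(log_terms - m).sum()))


def _normalize(genes: Iterable[str]) -> set[str]:
    return {g.strip().upper() for g in genes if g and g.strip()}


@dataclass
class EnrichmentResult:
    """Counts, fold enrichment and hypergeometric tail probability."""

    universe_n: int  # N: genes captured
    candidate_k: int  # K: candidate-list genes in the universe
    hit_n: int  # n: genes with surviving variants
    overlap: int  # k: candidate genes among the hits
    fold: float
    p_value: float

    def summary(self) -> str:
        lines = [
            "Candidate-gene enrichment (hypergeometric upper tail)",
            f"  universe (N):          {self.universe_n}",
            f"  candidates in universe (K): {self.candidate_k}",
            f"  hit genes (n):         {self.hit_n}",
            f"  candidate hits (k):    {self.overlap}",
            f"  hit rate in list:      {self.overlap / self.candidate_k:.2%}"
            if self.candidate_k
            else "  hit rate in list:      n/a",
            f"  hit rate overall:      {self.hit_n / self.universe_n:.2%}",
            f"  fold enrichment:       {self.fold:.2f}",
            f"  P(X >= k):             {self.p_value:.3g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "universe_n": self.universe_n,
            "candidate_k": self.candidate_k,
            "hit_n": self.hit_n,
            "overlap": self.overlap,
            "fold": self.fold,
            "p_value": self.p_value,
        }


def enrichment(
    hit_genes: Iterable[str],
    candidate_genes: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Enrichment of ``candidate_genes`` among ``hit_genes`` within ``universe``.

    Gene symbols are compared case-insensitively after whitespace
    stripping.  Hits must lie within the universe; candidates are
    intersected with it before counting.
    """
    uni = _normalize(universe)
    if not uni:
        raise ValueError("empty gene universe")
    hits = _normalize(hit_genes)
    stray = hits - uni
    if stray:
        raise ValueError(
            f"{len(stray)} hit genes outside the universe, e.g. "
            f"{sorted(stray)[:3]}"
        )
    cand = _normalize(candidate_genes) & uni
    if not cand:
        raise ValueError("candidate list does not intersect the universe")
    N, K, n = len(uni), len(cand), len(hits)
    k = len(hits & cand)
    fold = (k / K) / (n / N) if n else float("nan")
    p = hypergeometric_tail(k, K, n, N) if n else 1.0
    return EnrichmentResult(
        universe_n=N, candidate_k=K, hit_n=n, overlap=k, fold=fold, p_value=p
    )


def permutation_null(
    observed_overlap: int,
    n_hits: int,
    candidate_genes: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical tail probability by resampling hit sets from the universe.

    Draws ``n_perm`` uniform hit sets of size ``n_hits`` without
    replacement; returns (1 + #{overlap >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uni = sorted(_normalize(universe))
    cand = _normalize(candidate_genes) & set(uni)
    is_cand = np.array([g in cand for g in uni])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        pick = rng.choice(len(uni), size=n_hits, replace=False)
        if int(is_cand[pick].sum()) >= observed_overlap:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)
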