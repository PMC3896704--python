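"""Windowed pairwise-r2 LD pruning (PLINK ``--indep-pairwise`` semantics)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable, MapMarker

__all__ = ["PruneParams", "genotype_r2", "ld_prune"]


@dataclass(frozen=True)
class PruneParams:
    """Greedy windowed pruning parameters (markers, not kb)."""

    window_size: int = 50
    step: int = 5
    r2_threshold: float = 0.5

    def __post_init__(self):
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 1 <= self.step <= self.window_size:
            raise ValueError("step must be in [1, window_size]")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over samples where
    both are called.  None when undefined (monomorphic or <2 shared calls)."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return None
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    gt: GenotypeTable,
    markers: Sequence[MapMarker],
    params: PruneParams = PruneParams(),
) -> list[str]:
    """Greedy windowed pruning of correlated markers; returns retained ids
    in map order.

    Windows of ``window_size`` markers advance by ``step`` along each
    chromosome.  Within a window, while any retained pair has r2 above the
    threshold, the later marker of the (first such, in index order) pair is
    removed.  Markers with undefined r2 (monomorphic) are never removed on
    account of correlation.  The retained set is invariant to sample order
    because r2 is.
    """
    if [m.marker_id for m in markers] != gt.marker_ids:
        raise ValueError("marker list does not match genotype table")
    removed = np.zeros(gt.n_markers, dtype=bool)

    # chromosome boundaries (markers are map-ordered within chromosome)
    spans: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(markers) + 1):
        if i == len(markers) or markers[i].chrom != markers[start].chrom:
            spans.append((start, i))
            start = i

    for lo, hi in spans:
        w0 = lo
        while True:
            w1 = min(w0 + params.window_size, hi)
            idx = [i for i in range(w0, w1) if not removed[i]]
            changed = True
            while changed:
                changed = False
                for ai in range(len(idx)):
                    i = idx[ai]
                    if removed[i]:
                        continue
                    for bj in range(ai + 1, len(idx)):
                        j = idx[bj]
                        if removed[j]:
                            continue
                        r2 = genotype_r2(gt.calls[i], gt.calls[j])
                        if r2 is not None and r2 > params.r2_threshold:
                            removed[j] = True
                            changed = True
                if changed:
                    idx = [i for i in idx if not removed[i]]
            if w1 == hi:
                break
            w0 += params.step
    return [m.marker_id for k, m in enumerate(markers) if not removed[k]]
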