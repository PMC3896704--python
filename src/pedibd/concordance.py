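"""Cross-platform genotype concordance and call-rate QC.

Sample identity between sequencing and array platforms is confirmed by
comparing genotypes at shared sites.  Sites are matched on (chromosome,
position); when the two platforms encode opposite alleles as the
alternate, dosages are complemented (g -> 2 - g) before comparison, so a
pure labelling swap scores 100% concordant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable, MapMarker

__all__ = ["ConcordanceReport", "genotype_concordance", "call_rate_qc"]


@dataclass
class ConcordanceReport:
    per_sample: dict[str, float]
    overall_mean: float
    n_sites_compared: int


def _harmonize(
    markers_a: Sequence[MapMarker], markers_b: Sequence[MapMarker]
) -> list[tuple[int, int, bool]]:
    """Indices of shared sites and whether b's dosage must be complemented."""
    by_pos = {
        (m.chrom, m.position_bp): (i, m) for i, m in enumerate(markers_a)
    }
    shared: list[tuple[int, int, bool]] = []
    for j, mb in enumerate(markers_b):
        hit = by_pos.get((mb.chrom, mb.position_bp))
        if hit is None:
            continue
        i, ma = hit
        if (ma.ref_allele, ma.alt_allele) == (mb.ref_allele, mb.alt_allele):
            shared.append((i, j, False))
        elif (ma.ref_allele, ma.alt_allele) == (mb.alt_allele, mb.ref_allele):
            shared.append((i, j, True))
        # different alleles entirely: not the same site, skip
    return shared


def genotype_concordance(
    table_a: GenotypeTable,
    table_b: GenotypeTable,
    markers_a: Sequence[MapMarker],
    markers_b: Sequence[MapMarker],
) -> ConcordanceReport:
    """Per-sample identical-genotype fraction over co-called shared sites.

    Sites missing on either platform for a sample are excluded from that
    sample's denominator; ``overall_mean`` is the unweighted mean across
    shared samples.  Symmetric in its two (table, marker) pairs.
    """
    if [m.marker_id for m in markers_a] != table_a.marker_ids or [
        m.marker_id for m in markers_b
    ] != table_b.marker_ids:
        raise ValueError("marker lists do not match genotype tables")
    shared = _harmonize(markers_a, markers_b)
    if not shared:
        raise ValueError("no shared sites between the two platforms")
    samples = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    if not samples:
        raise ValueError("no shared samples between the two platforms")

    ia = [s[0] for s in shared]
    ib = [s[1] for s in shared]
    flip = np.array([s[2] for s in shared])

    per_sample: dict[str, float] = {}
    for sid in samples:
        a = table_a.column(sid)[ia]
        b = table_b.column(sid)[ib].copy()
        called = (a != MISSING) & (b != MISSING)
        b = np.where(flip & called, 2 - b, b)
        if called.sum() == 0:
            continue
        per_sample[sid] = float((a[called] == b[called]).mean())
    if not per_sample:
        raise ValueError("no co-called genotypes in any shared sample")
    return ConcordanceReport(
        per_sample=per_sample,
        overall_mean=float(np.mean(list(per_sample.values()))),
        n_sites_compared=len(shared),
    )


def call_rate_qc(table: GenotypeTable, min_rate: float = 0.98) -> dict[str, bool]:
    """Per-sample pass/fail: non-missing fraction >= ``min_rate`` (inclusive)."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0,1]")
    rates = table.call_rate()
    return {
        sid: bool(rates[i] >= min_rate) for i, sid in enumerate(table.sample_ids)
    }
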