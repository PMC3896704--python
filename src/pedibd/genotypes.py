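"""Genotype matrices, genetic-map markers, and Mendelian consistency checks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .pedigree import MALE, Pedigree, PedigreeError

__all__ = ["MISSING", "MapMarker", "GenotypeTable", "mendelian_check"]

MISSING = -1  # missing genotype sentinel in `calls`


@dataclass(frozen=True)
class MapMarker:
    """One biallelic array marker with physical and genetic coordinates.

    ``panel_af`` is the alternate-allele frequency in the reference panel;
    it plays the role of the external panel frequencies that weight the
    founder-allele prior in the multipoint sharing model.
    """

    marker_id: str
    chrom: str
    position_bp: int
    position_cM: float
    ref_allele: str = "A"
    alt_allele: str = "G"
    panel_af: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.panel_af <= 1.0:
            raise ValueError(f"panel_af outside [0,1]: {self.panel_af}")


def check_map_sorted(markers: Sequence[MapMarker]) -> None:
    """Markers must increase strictly in both bp and cM within a chromosome."""
    by_chrom: dict[str, MapMarker] = {}
    for m in markers:
        prev = by_chrom.get(m.chrom)
        if prev is not None and (
            m.position_bp <= prev.position_bp or m.position_cM < prev.position_cM
        ):
            raise ValueError(
                f"map not sorted on {m.chrom}: {prev.marker_id} -> {m.marker_id}"
            )
        by_chrom[m.chrom] = m


class GenotypeTable:
    """Unphased biallelic genotypes (alt-allele dosage) for a set of samples.

    ``calls`` has shape (n_markers, n_samples) with entries in
    {0, 1, 2, MISSING}.  Male X-chromosome calls use the diploid
    hemizygous convention {0, 2, MISSING}.  ``phase``, present only when the
    table was produced by simulation, holds ordered (paternal, maternal)
    alt-allele indicators with shape (n_markers, n_samples, 2).
    """

    def __init__(
        self,
        marker_ids: Sequence[str],
        sample_ids: Sequence[str],
        calls: np.ndarray,
        phase: Optional[np.ndarray] = None,
    ):
        self.marker_ids = list(marker_ids)
        self.sample_ids = list(sample_ids)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(self.marker_ids)}, {len(self.sample_ids)})"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2,missing}")
        self.calls = calls
        if phase is not None:
            phase = np.asarray(phase, dtype=np.int8)
            if phase.shape != calls.shape + (2,):
                raise ValueError("phase shape must be calls shape + (2,)")
        self.phase = phase

    # ------------------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample_id)]

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeTable":
        ix = [self.marker_index(m) for m in marker_ids]
        return GenotypeTable(
            [self.marker_ids[i] for i in ix],
            self.sample_ids,
            self.calls[ix],
            None if self.phase is None else self.phase[ix],
        )

    def call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=0)

    def drop_phase(self) -> "GenotypeTable":
        return GenotypeTable(self.marker_ids, self.sample_ids, self.calls.copy())


def mendelian_check(
    ped: Pedigree,
    gt: GenotypeTable,
    x_marker_ids: Iterable[str] = (),
) -> list[tuple[str, str, str]]:
    """Child/parent genotype incompatibilities under biallelic inheritance.

    Returns (marker_id, child_id, parent_id) tuples.  A pair violates when
    the child cannot have received any allele from that parent: opposite
    homozygotes on autosomes.  On X markers (``x_marker_ids``) father->son
    pairs transmit no X and are never checked; sons are checked against the
    mother as hemizygous, daughters against the father's single allele.
    Missing calls never violate.
    """
    for sid in gt.sample_ids:
        if sid not in ped:
            raise PedigreeError(f"sample {sid!r} is not a member of {ped.family_id!r}")
    x_set = set(x_marker_ids)
    is_x = np.array([m in x_set for m in gt.marker_ids], dtype=bool)
    in_table = set(gt.sample_ids)

    violations: list[tuple[str, str, str]] = []
    for child in sorted(ped.nonfounders, key=lambda m: m.person_id):
        if child.person_id not in in_table:
            continue
        c = gt.column(child.person_id)
        for parent_id in (child.father_id, child.mother_id):
            if parent_id not in in_table:
                continue
            p = gt.column(parent_id)
            opposite = ((c == 0) & (p == 2)) | ((c == 2) & (p == 0))
            parent_is_father = parent_id == child.father_id
            if parent_is_father and child.sex == MALE:
                # no father->son X transmission
                bad = opposite & ~is_x
            else:
                bad = opposite
            for i in np.flatnonzero(bad):
                violations.append(
                    (gt.marker_ids[i], child.person_id, parent_id)
                )
    return violations
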