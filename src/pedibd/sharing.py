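"""Multipoint all-affected IBD sharing via an inheritance-vector HMM.

The hidden state at each marker is the inheritance vector ``v`` with one bit
per meiosis (bit 0 = the parent transmitted their own paternal allele,
1 = maternal).  Between adjacent markers each bit flips independently with
the Haldane recombination fraction for the inter-marker map distance;
emissions sum over founder-allele assignments weighted by the panel allele
frequency.  The per-marker output is the posterior probability that the
inheritance vector implies a founder allele carried by every affected
member of the family — the quantity the sliding-window segment caller
consumes.

On the X chromosome the vector holds one bit per non-founder (the maternal
X meiosis): fathers pass their single X to daughters deterministically and
nothing to sons.  Male X genotypes use the diploid {0,2} hemizygous
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable, MapMarker, check_map_sorted
from .pedigree import FEMALE, MALE, Pedigree, PedigreeError, _topological_order

__all__ = [
    "SharingProfile",
    "CapacityError",
    "haldane_theta",
    "compute_sharing",
]

logger = logging.getLogger(__name__)

X_LABELS = {"X", "chrX", "x", "23"}

# emission tensor chunk bound: n_assignments * state-chunk entries
_CHUNK_ENTRIES = 1 << 24


class CapacityError(PedigreeError):
    """Pedigree exceeds the configured meiosis cap."""


@dataclass
class SharingProfile:
    """Per-marker posterior that all affected share a founder allele IBD."""

    family_id: str
    chrom: str
    marker_ids: list[str]
    sharing: np.ndarray

    def __post_init__(self):
        self.sharing = np.asarray(self.sharing, dtype=float)
        if len(self.sharing) != len(self.marker_ids):
            raise ValueError("sharing length != marker count")
        if len(self.sharing) and (
            self.sharing.min() < -1e-9 or self.sharing.max() > 1 + 1e-9
        ):
            raise ValueError("sharing values outside [0,1]")
        self.sharing = np.clip(self.sharing, 0.0, 1.0)


def haldane_theta(d_morgans) -> np.ndarray:
    """Haldane map function: theta = (1 - exp(-2d)) / 2, d in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def is_x_chrom(chrom: str) -> bool:
    return chrom in X_LABELS


# ---------------------------------------------------------------------------
# descent structure


class _Descent:
    """Founder-allele index carried by every member under every state.

    For autosomes each member has (paternal, maternal) index arrays of
    shape (n_states,); on X, males carry a single index array and females a
    (paternal, maternal) pair.  Founder alleles are numbered in sorted
    founder order.
    """

    def __init__(self, ped: Pedigree, x: bool):
        self.ped = ped
        self.x = x
        founders = sorted(ped.founders, key=lambda m: m.person_id)
        nonfounders = sorted(ped.nonfounders, key=lambda m: m.person_id)

        self.allele_labels: list[tuple[str, int]] = []
        slot: dict[tuple[str, int], int] = {}
        for f in founders:
            n_slots = 1 if (x and f.sex == MALE) else 2
            for h in range(n_slots):
                slot[(f.person_id, h)] = len(self.allele_labels)
                self.allele_labels.append((f.person_id, h))
        self.n_alleles = len(self.allele_labels)

        if x:
            self.bit_of = {ind.person_id: i for i, ind in enumerate(nonfounders)}
            self.n_bits = len(nonfounders)
        else:
            bits: dict[tuple[str, str], int] = {}
            for i, ind in enumerate(nonfounders):
                bits[(ind.person_id, "paternal")] = 2 * i
                bits[(ind.person_id, "maternal")] = 2 * i + 1
            self.bit_of = bits
            self.n_bits = 2 * len(nonfounders)

        self.n_states = 1 << self.n_bits
        states = np.arange(self.n_states)

        # alleles[pid] -> tuple of (n_states,) arrays (len 1 for X males)
        self.alleles: dict[str, tuple[np.ndarray, ...]] = {}
        for pid in _topological_order(ped):
            ind = ped.members[pid]
            if ind.is_founder:
                if x and ind.sex == MALE:
                    arrs = (np.full(self.n_states, slot[(pid, 0)], dtype=np.int16),)
                else:
                    arrs = (
                        np.full(self.n_states, slot[(pid, 0)], dtype=np.int16),
                        np.full(self.n_states, slot[(pid, 1)], dtype=np.int16),
                    )
            elif x:
                mo = self.alleles[ind.mother_id]
                b = (states >> self.bit_of[pid]) & 1
                mat = np.where(b == 0, mo[0], mo[-1]).astype(np.int16)
                if ind.sex == MALE:
                    arrs = (mat,)
                else:
                    fa = self.alleles[ind.father_id]
                    arrs = (fa[0], mat)  # father's single X passes intact
            else:
                fa = self.alleles[ind.father_id]
                mo = self.alleles[ind.mother_id]
                bp = (states >> self.bit_of[(pid, "paternal")]) & 1
                bm = (states >> self.bit_of[(pid, "maternal")]) & 1
                arrs = (
                    np.where(bp == 0, fa[0], fa[1]).astype(np.int16),
                    np.where(bm == 0, mo[0], mo[1]).astype(np.int16),
                )
            self.alleles[pid] = arrs

    def all_affected_share(self) -> np.ndarray:
        """Boolean (n_states,): some founder allele carried by every affected."""
        affected = self.ped.affected_ids()
        if not affected:
            raise PedigreeError("no affected members")
        share = np.zeros(self.n_states, dtype=bool)
        for j in range(self.n_alleles):
            carried = np.ones(self.n_states, dtype=bool)
            for pid in affected:
                arrs = self.alleles[pid]
                c = arrs[0] == j
                for a in arrs[1:]:
                    c = c | (a == j)
                carried &= c
                if not carried.any():
                    break
            share |= carried
            if share.all():
                break
        return share


def _emissions(
    desc: _Descent,
    gt: GenotypeTable,
    markers: Sequence[MapMarker],
    genotype_error: float,
) -> np.ndarray:
    """Per-marker, per-state emission probabilities (n_markers, n_states).

    emission(v, marker) = sum over founder-allele assignments of the
    assignment prior (product of per-allele panel frequencies) times the
    probability of the observed genotypes given implied dosages.  With
    ``genotype_error`` e > 0 an observed genotype matches an implied one
    with weight (1-e) and mismatches with weight e/2.
    """
    ped = desc.ped
    typed = [
        sid
        for sid in gt.sample_ids
        if sid in ped.members and ped.members[sid].genotyped
    ]
    a = desc.n_alleles
    n_assign = 1 << a
    n_states = desc.n_states
    n_markers = len(markers)

    AB = ((np.arange(n_assign)[:, None] >> np.arange(a)) & 1).astype(np.int8)
    popcnt = AB.sum(axis=1)

    afs = np.array([m.panel_af for m in markers], dtype=float)
    afs = np.clip(afs, 1e-12, 1 - 1e-12)
    # prior over assignments per marker: p^popcnt * (1-p)^(a-popcnt)
    log_prior = np.log(afs)[:, None] * popcnt[None, :] + np.log1p(-afs)[
        :, None
    ] * (a - popcnt)[None, :]
    prior = np.exp(log_prior)  # (n_markers, n_assign)

    calls = np.stack([gt.column(sid) for sid in typed], axis=1)  # (mk, typed)
    if desc.x:
        male = [ped.members[sid].sex == MALE for sid in typed]
        bad = np.isin(calls, 1) & np.array(male)[None, :]
        if bad.any():
            logger.warning(
                "family %s: %d heterozygous male X calls treated as missing",
                ped.family_id,
                int(bad.sum()),
            )
            calls = np.where(bad, MISSING, calls)

    E = np.empty((n_markers, n_states), dtype=float)
    chunk = max(1, min(n_states, _CHUNK_ENTRIES // n_assign))
    e = float(genotype_error)
    for s0 in range(0, n_states, chunk):
        s1 = min(s0 + chunk, n_states)
        implied = []
        for sid in typed:
            arrs = desc.alleles[sid]
            if len(arrs) == 1:  # hemizygous male X, diploid coding
                g = 2 * AB[:, arrs[0][s0:s1]]
            else:
                g = AB[:, arrs[0][s0:s1]] + AB[:, arrs[1][s0:s1]]
            implied.append(g)  # (n_assign, s1-s0) int8
        for j in range(n_markers):
            if e == 0.0:
                mask = np.ones((n_assign, s1 - s0), dtype=bool)
                for t, g in enumerate(calls[j]):
                    if g != MISSING:
                        mask &= implied[t] == g
                E[j, s0:s1] = prior[j] @ mask
            else:
                w = np.ones((n_assign, s1 - s0), dtype=float)
                for t, g in enumerate(calls[j]):
                    if g != MISSING:
                        w *= np.where(implied[t] == g, 1.0 - e, 0.5 * e)
                E[j, s0:s1] = prior[j] @ w
    return E


def _mix_bits(f: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """Apply the independent-bit-flip transition operator to a state vector."""
    if theta == 0.0 or n_bits == 0:
        return f
    g = f.reshape((2,) * n_bits)
    for axis in range(n_bits):
        g = (1.0 - theta) * g + theta * np.flip(g, axis=axis)
    return g.reshape(-1)


def compute_sharing(
    ped: Pedigree,
    gt: GenotypeTable,
    markers: Sequence[MapMarker],
    *,
    genotype_error: float = 0.0,
    max_meioses: int = 20,
) -> SharingProfile:
    """Forward-backward posterior of the all-affected sharing event.

    ``markers`` must belong to a single chromosome, be map-ordered, and
    match ``gt.marker_ids``.  Markers at which every sample is missing (or
    whose observations are impossible under the pedigree with
    ``genotype_error`` = 0) contribute a uniform emission.
    """
    if not markers:
        raise ValueError("no markers")
    chroms = {m.chrom for m in markers}
    if len(chroms) > 1:
        raise ValueError(f"markers span several chromosomes: {sorted(chroms)}")
    check_map_sorted(markers)
    if [m.marker_id for m in markers] != gt.marker_ids:
        raise ValueError("marker list does not match genotype table")
    chrom = markers[0].chrom
    x = is_x_chrom(chrom)

    affected = ped.affected_ids()
    if not affected:
        raise PedigreeError(f"family {ped.family_id!r} has no affected members")
    typed_affected = [
        pid for pid in affected if pid in gt.sample_ids and ped.members[pid].genotyped
    ]
    if not typed_affected:
        raise PedigreeError(
            f"family {ped.family_id!r}: no affected member is genotyped"
        )

    desc = _Descent(ped, x)
    if desc.n_bits > max_meioses:
        raise CapacityError(
            f"family {ped.family_id!r}: {desc.n_bits} meioses "
            f"exceeds cap {max_meioses}"
        )

    share = desc.all_affected_share().astype(float)
    E = _emissions(desc, gt, markers, genotype_error)
    # impossible/blank markers: uniform emission
    dead = E.sum(axis=1) == 0.0
    if dead.any():
        E[dead] = 1.0

    n = len(markers)
    n_states = desc.n_states
    d = np.diff([m.position_cM for m in markers]) / 100.0
    thetas = haldane_theta(d)

    prior = np.full(n_states, 1.0 / n_states)

    fwd = np.empty((n, n_states))
    f = prior * E[0]
    s = f.sum()
    fwd[0] = f / s
    for j in range(1, n):
        f = _mix_bits(fwd[j - 1], float(thetas[j - 1]), desc.n_bits) * E[j]
        s = f.sum()
        if s == 0.0:  # pathological; drop this marker's evidence
            f = _mix_bits(fwd[j - 1], float(thetas[j - 1]), desc.n_bits)
            s = f.sum()
        fwd[j] = f / s

    sharing = np.empty(n)
    b = np.ones(n_states)
    post = fwd[n - 1]
    sharing[n - 1] = (post / post.sum()) @ share
    for j in range(n - 2, -1, -1):
        b = _mix_bits(b * E[j + 1], float(thetas[j]), desc.n_bits)
        s = b.sum()
        if s > 0:
            b = b / s
        post = fwd[j] * b
        tot = post.sum()
        if tot == 0.0:
            post = fwd[j]
            tot = post.sum()
        sharing[j] = (post / tot) @ share

    return SharingProfile(
        family_id=ped.family_id,
        chrom=chrom,
        marker_ids=[m.marker_id for m in markers],
        sharing=sharing,
    )
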