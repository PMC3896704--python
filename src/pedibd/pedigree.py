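"""Pedigree structures for multiplex-family IBD analysis.

A pedigree is a directed family graph with sex and affection status.  The
families this package targets are outbred, multiplex (several affected
relatives, at least one affected cousin pair) and fully specified: every
member either has both parents in the pedigree or is a founder.  The
pedigree's list of meioses — one paternal and one maternal transmission per
non-founder — indexes the inheritance-vector hidden state used by the
multipoint IBD model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Individual",
    "Pedigree",
    "ValidationReport",
    "Meiosis",
    "PedigreeError",
    "validate_pedigree",
    "enumerate_meioses",
    "xlinked_compatible",
    "obligate_carriers",
    "ObligateCarrierResult",
]

MALE = "male"
FEMALE = "female"
AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Structural problem with a pedigree or its use."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``affection`` is three-valued: individuals with an uncertain phenotype
    (``unknown``) are excluded from every affected-sharing computation, so
    they contribute genotype information but never constrain segregation.
    """

    person_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = MALE
    affection: str = UNKNOWN
    genotyped: bool = True
    sequenced: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Meiosis:
    """A single transmission: ``parent_role`` is 'paternal' or 'maternal'."""

    child_id: str
    parent_role: str

    @property
    def parent_attr(self) -> str:
        return "father_id" if self.parent_role == "paternal" else "mother_id"


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


class Pedigree:
    """Directed family graph; the unit of analysis.

    Parameters
    ----------
    family_id
        Family label shared by all members.
    members
        Iterable of :class:`Individual`; order is preserved.
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.person_id in self.members:
                raise PedigreeError(
                    f"duplicate person id {ind.person_id!r} in family {family_id!r}"
                )
            self.members[ind.person_id] = ind

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.members

    def __getitem__(self, person_id: str) -> Individual:
        return self.members[person_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members.values() if not m.is_founder]

    def affected_ids(self) -> list[str]:
        return sorted(
            m.person_id for m in self.members.values() if m.affection == AFFECTED
        )

    def father(self, person_id: str) -> Optional[Individual]:
        fid = self.members[person_id].father_id
        return self.members.get(fid) if fid is not None else None

    def mother(self, person_id: str) -> Optional[Individual]:
        mid = self.members[person_id].mother_id
        return self.members.get(mid) if mid is not None else None

    def children(self, person_id: str) -> list[Individual]:
        return [
            m
            for m in self.members.values()
            if person_id in (m.father_id, m.mother_id)
        ]

    # -- derived structure -------------------------------------------------
    @property
    def meioses(self) -> list[Meiosis]:
        return enumerate_meioses(self)

    @property
    def n_meioses(self) -> int:
        return 2 * len(self.nonfounders)

    def ancestors(self, person_id: str) -> set[str]:
        """All strict ancestors reachable through parent links."""
        out: set[str] = set()
        stack = [person_id]
        while stack:
            cur = self.members[stack.pop()]
            for pid in (cur.father_id, cur.mother_id):
                if pid is not None and pid in self.members and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def validate(self) -> ValidationReport:
        return validate_pedigree(self)


def validate_pedigree(ped: Pedigree) -> ValidationReport:
    """Check structural invariants; violations are reported, never raised.

    The report is empty iff: every parent reference resolves to a member of
    the right sex, nobody is a half-founder (exactly one parent known),
    parent links are acyclic, and the pedigree contains no loop
    (consanguinity) — any individual with two distinct paths to a common
    ancestor couple is out of scope for this package.
    """
    report = ValidationReport()
    if not ped.members:
        raise PedigreeError("pedigree has no members")
    for ind in ped.members.values():
        if (ind.father_id is None) != (ind.mother_id is None):
            report.add(f"{ind.person_id}: half-founder (exactly one parent known)")
        for pid, want_sex, role in (
            (ind.father_id, MALE, "father"),
            (ind.mother_id, FEMALE, "mother"),
        ):
            if pid is None:
                continue
            parent = ped.members.get(pid)
            if parent is None:
                report.add(f"{ind.person_id}: missing {role} {pid!r}")
            elif parent.sex != want_sex:
                report.add(
                    f"{ind.person_id}: {role} {pid!r} has sex {parent.sex!r}"
                )
        if ind.sex not in (MALE, FEMALE):
            report.add(f"{ind.person_id}: invalid sex {ind.sex!r}")

    # cycle detection over the child -> parent graph
    WHITE, GREY, BLACK = 0, 1, 2
    color = {pid: WHITE for pid in ped.members}

    def visit(pid: str) -> bool:
        color[pid] = GREY
        ind = ped.members[pid]
        for parent in (ind.father_id, ind.mother_id):
            if parent is None or parent not in ped.members:
                continue
            if color[parent] == GREY:
                return True
            if color[parent] == WHITE and visit(parent):
                return True
        color[pid] = BLACK
        return False

    for pid in ped.members:
        if color[pid] == WHITE and visit(pid):
            report.add(f"cycle in parent links involving {pid!r}")
            break

    if report.ok:
        # pedigree loops: a couple reachable as ancestors along two disjoint
        # child paths.  Outbred test: each non-founder's paternal and
        # maternal ancestor sets must be disjoint.
        for ind in ped.nonfounders:
            pa = ped.ancestors(ind.father_id) | {ind.father_id}
            ma = ped.ancestors(ind.mother_id) | {ind.mother_id}
            shared = pa & ma
            if shared:
                report.add(
                    f"{ind.person_id}: inbreeding loop through {sorted(shared)}"
                )
    return report


def enumerate_meioses(ped: Pedigree) -> list[Meiosis]:
    """Deterministic meiosis ordering: by child id, paternal before maternal.

    The position of each meiosis in this list is the bit index of the
    inheritance vector, so the ordering is part of the model contract.
    """
    report = validate_pedigree(ped)
    if not report.ok:
        raise PedigreeError(
            f"invalid pedigree {ped.family_id!r}: {report.violations}"
        )
    out: list[Meiosis] = []
    for ind in sorted(ped.nonfounders, key=lambda m: m.person_id):
        out.append(Meiosis(ind.person_id, "paternal"))
        out.append(Meiosis(ind.person_id, "maternal"))
    return out


def xlinked_compatible(ped: Pedigree) -> bool:
    """Could all affected members be explained by one X-linked founder allele?

    True iff some founder X haplotype can reach every affected member:
    affected males hemizygous, affected females carrying at least one copy.
    An affected father/son pair always fails (fathers pass no X to sons).
    Decided by brute-force X gene-dropping over the descent-pattern space,
    which is exact and cheap at pedigree scale.
    """
    affected = ped.affected_ids()
    if len(affected) < 2:
        raise PedigreeError("xlinked_compatible requires >= 2 affected members")

    # X founder alleles: one per male founder, two per female founder.
    allele_ix: dict[tuple[str, int], int] = {}
    for f in sorted(ped.founders, key=lambda m: m.person_id):
        if f.sex == FEMALE:
            allele_ix[(f.person_id, 0)] = len(allele_ix)
            allele_ix[(f.person_id, 1)] = len(allele_ix)
        else:
            allele_ix[(f.person_id, 0)] = len(allele_ix)

    # maternal meioses (the only X transmissions with a free choice)
    mat_meioses = sorted(m.person_id for m in ped.nonfounders)
    n_bits = len(mat_meioses)
    bit_of = {pid: i for i, pid in enumerate(mat_meioses)}

    order = _topological_order(ped)

    for v in range(1 << n_bits):
        # alleles[pid] -> tuple of founder-allele indices carried on X
        alleles: dict[str, tuple[int, ...]] = {}
        for pid in order:
            ind = ped.members[pid]
            if ind.is_founder:
                if ind.sex == FEMALE:
                    alleles[pid] = (
                        allele_ix[(pid, 0)],
                        allele_ix[(pid, 1)],
                    )
                else:
                    alleles[pid] = (allele_ix[(pid, 0)],)
            else:
                mother = alleles[ind.mother_id]
                pick = (v >> bit_of[pid]) & 1 if len(mother) == 2 else 0
                mat = mother[pick]
                if ind.sex == MALE:
                    alleles[pid] = (mat,)
                else:
                    father = alleles[ind.father_id]
                    alleles[pid] = (father[0], mat)
        carried = [set(alleles[a]) for a in affected]
        if set.intersection(*carried):
            return True
    return False


def _topological_order(ped: Pedigree) -> list[str]:
    """Members ordered parents-before-children."""
    order: list[str] = []
    done: set[str] = set()

    def visit(pid: str) -> None:
        if pid in done:
            return
        ind = ped.members[pid]
        if ind.father_id is not None:
            visit(ind.father_id)
        if ind.mother_id is not None:
            visit(ind.mother_id)
        done.add(pid)
        order.append(pid)

    for pid in sorted(ped.members):
        visit(pid)
    return order


@dataclass
class ObligateCarrierResult:
    """Unsequenced individuals forced to carry a shared heterozygous variant."""

    carriers: set[str]
    ambiguous: bool = False

    def __iter__(self):
        return iter(self.carriers)

    def __eq__(self, other):
        if isinstance(other, ObligateCarrierResult):
            return (self.carriers, self.ambiguous) == (
                other.carriers,
                other.ambiguous,
            )
        return self.carriers == other


def obligate_carriers(ped: Pedigree, carriers: set[str]) -> ObligateCarrierResult:
    """Individuals who must carry a variant shared IBD by ``carriers``.

    Under a heterozygous single-founder-origin model, everyone on a
    transmission path from the most recent common transmitting ancestor(s)
    down to each observed carrier is an obligate carrier.  Individuals are
    returned only if they are not themselves in ``carriers``.  For a full
    sibship the variant may have come through either parent; in that case
    both parents are returned and the result is flagged ``ambiguous``.
    """
    carriers = set(carriers)
    for pid in carriers:
        if pid not in ped.members:
            raise PedigreeError(f"unknown carrier {pid!r} in family {ped.family_id!r}")
    if len(carriers) < 2:
        return ObligateCarrierResult(set())

    # Candidate transmitting ancestors: common ancestors of all carriers
    # (a carrier may itself be the transmitting ancestor of the others).
    anc_sets = [ped.ancestors(pid) | {pid} for pid in sorted(carriers)]
    common = set.intersection(*anc_sets)
    if not common:
        raise PedigreeError("carriers share no common ancestor")
    # most recent: no member of `common` is an ancestor of another kept one
    mrca = {
        a
        for a in common
        if not any(a in ped.ancestors(b) for b in common if b != a)
    }

    # For each MRCA, collect union of all down-paths to each carrier; the
    # obligate set under that origin is the union of path interiors.  With
    # several equally recent origins (e.g. a founder couple, or either
    # parent of a sibship) take the intersection of their obligate sets and
    # flag ambiguity for what differs.
    def paths_down(src: str, dst: str) -> list[list[str]]:
        if src == dst:
            return [[dst]]
        out = []
        for child in ped.children(src):
            for tail in paths_down(child.person_id, dst):
                out.append([src] + tail)
        return out

    per_origin: list[set[str]] = []
    for origin in sorted(mrca):
        members: set[str] = set()
        ok = True
        for pid in sorted(carriers):
            ps = paths_down(origin, pid)
            if not ps:
                ok = False
                break
            # on every path: nodes that appear in all paths to this carrier
            members |= set.intersection(*(set(p) for p in ps))
        if ok:
            per_origin.append(members)
    if not per_origin:
        return ObligateCarrierResult(set())

    certain = set.intersection(*per_origin) - carriers
    union = set.union(*per_origin) - carriers
    # An obligate carrier carries the variant under every consistent origin:
    # the intersection across origins.  When that is empty (a full sibship,
    # where either parent could have transmitted) the candidate set is
    # returned instead, flagged ambiguous rather than guessed.
    if certain:
        return ObligateCarrierResult(certain)
    return ObligateCarrierResult(union, ambiguous=bool(union))
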