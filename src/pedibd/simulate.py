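"""Synthetic study generator: pedigrees, gene-dropped array genotypes,
injected causal variants, annotated exome tables and control cohorts.

The generator emulates the design this package analyzes: a set of extended
multiplex families (2-5 affected members, always including an affected
cousin pair), SNP-array markers with reference-panel allele frequencies,
exome variant calls annotated with effect class, panel/cohort frequencies
and call-quality fields, and an internal control cohort of 308 samples.
Causal variants are injected by conditional resampling of the gene-drop
descent (rejection sampling), so the marker data and the causal variant
share one coherent inheritance history — the recall target for the whole
pipeline.

All randomness flows from a single seed through ``numpy.random``
SeedSequence spawning; identical configuration and seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .filtering import HET, HOM, MODELS, XLINKED, VariantRecord
from .genotypes import MISSING, GenotypeTable, MapMarker, check_map_sorted
from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
    PedigreeError,
    _topological_order,
    xlinked_compatible,
)
from .sharing import haldane_theta, is_x_chrom

__all__ = [
    "ConfigError",
    "CausalSpec",
    "SimConfig",
    "AnnotatedVariantSet",
    "GeneDropResult",
    "TEMPLATE_CAPACITY",
    "generate_pedigree",
    "generate_markers",
    "gene_drop",
    "inject_causal_variant",
    "simulate_array_genotypes",
    "simulate_control_counts",
    "simulate_exome_table",
    "simulate_family",
    "simulate_study",
    "gene_of",
]

BP_PER_CM = 1_000_000
GENE_LENGTH_BP = 100_000
PANELS = ("AFR", "ASN", "EUR")  # three reference panels

_BASES = ("A", "C", "G", "T")


class ConfigError(ValueError):
    """Unsatisfiable or inconsistent simulation request."""


@dataclass(frozen=True)
class CausalSpec:
    """What to inject: effect class and inheritance model; the gene symbol
    is derived from the causal position unless given."""

    gene: Optional[str] = None
    effect: str = "missense"
    model: str = HET

    def __post_init__(self):
        if self.model not in MODELS:
            raise ConfigError(f"unknown inheritance model {self.model!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation settings.

    Defaults are desk scale: 6 families, 4 autosomes x 500 markers at
    0.25 cM spacing (2,000 markers), 5,000 exome variants per family and a
    308-sample control cohort.  ``n_affected_range`` spans the 2-5 affected
    members per family of the emulated design.
    """

    n_families: int = 6
    pedigree_template: str = "sib_cousins"
    n_affected_range: tuple[int, int] = (2, 5)
    n_autosomes: int = 4
    markers_per_chrom: int = 500
    marker_spacing_cM: float = 0.25
    include_x: bool = False
    panel_af_range: tuple[float, float] = (0.2, 0.8)
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.01
    n_exome_variants: int = 5000
    control_cohort_size: int = 308
    frac_low_vqslod: float = 0.05
    frac_low_depth: float = 0.02
    prob_affected_male: float = 0.9
    causal_spec: CausalSpec = CausalSpec()
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.genotype_error_rate,
            self.missing_rate,
            self.frac_low_vqslod,
            self.frac_low_depth,
            self.prob_affected_male,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability outside [0,1]: {p}")
        lo, hi = self.n_affected_range
        if not 2 <= lo <= hi:
            raise ConfigError("n_affected_range must satisfy 2 <= lo <= hi")
        if self.pedigree_template not in TEMPLATE_CAPACITY:
            raise ConfigError(f"unknown template {self.pedigree_template!r}")
        if self.causal_spec.model == XLINKED and not self.include_x:
            raise ConfigError("xlinked causal model requires include_x=True")

    @property
    def chromosomes(self) -> list[str]:
        out = [str(i + 1) for i in range(self.n_autosomes)]
        if self.include_x:
            out.append("X")
        return out

    @property
    def chrom_length_bp(self) -> int:
        return int(self.markers_per_chrom * self.marker_spacing_cM * BP_PER_CM)


@dataclass
class GeneDropResult:
    """Phased genotypes plus the founder-allele descent behind them.

    ``origins`` has shape (n_loci, n_samples, 2) holding founder-allele
    indices into ``founder_alleles`` (per-chromosome numbering; X males
    carry the same index twice).
    """

    table: GenotypeTable
    origins: np.ndarray
    founder_alleles: dict[str, list[tuple[str, int]]]  # chrom -> slot labels


@dataclass
class AnnotatedVariantSet:
    """Exome records plus the identifiers of injected causal variants."""

    records: list[VariantRecord]
    truth: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = {r.variant_id for r in self.records}
        if not self.truth <= ids:
            raise ValueError("truth variants missing from records")


# ---------------------------------------------------------------------------
# pedigree templates
#
# All templates link the affected descendants through female transmitting
# parents, so each is compatible with X-linked inheritance when the
# affected members' sexes allow it.  Capacity = (min, max) affected.

TEMPLATE_CAPACITY: dict[str, tuple[int, int]] = {
    "cousin_pair": (2, 2),
    "sib_cousins": (2, 6),
    "avuncular_plus_cousin": (3, 6),
    "second_cousin": (2, 4),
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_pedigree(template: str, n_affected: int, seed) -> Pedigree:
    """Build a valid multiplex pedigree with >= 1 affected cousin pair.

    Affected members' sexes are drawn (male-biased, reflecting the strong
    male skew of the emulated phenotype); structure is deterministic given
    the template and affected count.
    """
    if template not in TEMPLATE_CAPACITY:
        raise ConfigError(f"unknown template {template!r}")
    lo, hi = TEMPLATE_CAPACITY[template]
    if not lo <= n_affected <= hi:
        raise ConfigError(
            f"template {template!r} supports {lo}-{hi} affected, "
            f"requested {n_affected}"
        )
    rng = _rng(seed)

    def sex_draw() -> str:
        return MALE if rng.random() < 0.9 else FEMALE

    fam = "FAM"
    members: list[Individual] = []

    def add(pid, father=None, mother=None, sex=MALE, aff=UNAFFECTED):
        members.append(
            Individual(
                person_id=pid,
                family_id=fam,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affection=aff,
            )
        )

    if template in ("cousin_pair", "sib_cousins"):
        add("gf", sex=MALE)
        add("gm", sex=FEMALE)
        add("m1", "gf", "gm", FEMALE)
        add("m2", "gf", "gm", FEMALE)
        add("f1", sex=MALE)
        add("f2", sex=MALE)
        add("c101", "f1", "m1", sex_draw(), AFFECTED)
        add("c201", "f2", "m2", sex_draw(), AFFECTED)
        parents = [("f1", "m1", 1), ("f2", "m2", 2)]
        for k in range(n_affected - 2):
            f, m, br = parents[k % 2]
            add(f"c{br}{2 + k // 2:02d}", f, m, sex_draw(), AFFECTED)
    elif template == "avuncular_plus_cousin":
        add("gf", sex=MALE)
        add("gm", sex=FEMALE)
        add("m1", "gf", "gm", FEMALE)
        add("m2", "gf", "gm", FEMALE)
        add("u1", "gf", "gm", sex_draw(), AFFECTED)  # affected aunt/uncle
        add("f1", sex=MALE)
        add("f2", sex=MALE)
        add("c101", "f1", "m1", sex_draw(), AFFECTED)
        add("c201", "f2", "m2", sex_draw(), AFFECTED)
        parents = [("f1", "m1", 1), ("f2", "m2", 2)]
        for k in range(n_affected - 3):
            f, m, br = parents[k % 2]
            add(f"c{br}{2 + k // 2:02d}", f, m, sex_draw(), AFFECTED)
    else:  # second_cousin
        add("ggf", sex=MALE)
        add("ggm", sex=FEMALE)
        add("b1", "ggf", "ggm", FEMALE)
        add("b2", "ggf", "ggm", FEMALE)
        add("s1", sex=MALE)
        add("s2", sex=MALE)
        add("d1", "s1", "b1", FEMALE)
        add("d2", "s2", "b2", FEMALE)
        add("t1", sex=MALE)
        add("t2", sex=MALE)
        add("e101", "t1", "d1", sex_draw(), AFFECTED)
        add("e201", "t2", "d2", sex_draw(), AFFECTED)
        parents = [("t1", "d1", 1), ("t2", "d2", 2)]
        for k in range(n_affected - 2):
            f, m, br = parents[k % 2]
            add(f"e{br}{2 + k // 2:02d}", f, m, sex_draw(), AFFECTED)

    ped = Pedigree(fam, members)
    report = ped.validate()
    if not report.ok:  # defensive; templates are valid by construction
        raise PedigreeError(report.violations)
    return ped


# ---------------------------------------------------------------------------
# markers and genes


def generate_markers(config: SimConfig, seed) -> list[MapMarker]:
    """Evenly spaced array markers with panel frequencies drawn uniformly
    from ``panel_af_range`` (informative by construction)."""
    rng = _rng(seed)
    lo, hi = config.panel_af_range
    markers: list[MapMarker] = []
    for chrom in config.chromosomes:
        for i in range(config.markers_per_chrom):
            cm = i * config.marker_spacing_cM
            ref, alt = rng.choice(4, size=2, replace=False)
            markers.append(
                MapMarker(
                    marker_id=f"rs{chrom}_{i:05d}",
                    chrom=chrom,
                    position_bp=int(cm * BP_PER_CM) + 1,
                    position_cM=cm,
                    ref_allele=_BASES[ref],
                    alt_allele=_BASES[alt],
                    panel_af=float(rng.uniform(lo, hi)),
                )
            )
    return markers


def gene_of(chrom: str, pos: int) -> str:
    """Deterministic gene symbol for a position: contiguous 100-kb genes."""
    return f"G{chrom}X{(pos - 1) // GENE_LENGTH_BP:04d}"


def genes_in_genome(config: SimConfig) -> list[str]:
    out = []
    for chrom in config.chromosomes:
        n = (config.chrom_length_bp - 1) // GENE_LENGTH_BP + 1
        out.extend(f"G{chrom}X{i:04d}" for i in range(n))
    return out


# ---------------------------------------------------------------------------
# gene dropping


def _founder_slots(ped: Pedigree, x: bool) -> list[tuple[str, int]]:
    slots = []
    for f in sorted(ped.founders, key=lambda m: m.person_id):
        n = 1 if (x and f.sex == MALE) else 2
        slots.extend((f.person_id, h) for h in range(n))
    return slots


def _drop_chromosome(
    ped: Pedigree,
    markers: Sequence[MapMarker],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Origins (n_markers, n_samples, 2) of founder-allele indices for one
    chromosome, sample order = sorted member ids."""
    x = is_x_chrom(markers[0].chrom)
    slots = _founder_slots(ped, x)
    slot_ix = {lab: i for i, lab in enumerate(slots)}
    samples = sorted(ped.members)
    n = len(markers)
    cms = np.array([m.position_cM for m in markers])
    thetas = haldane_theta(np.diff(cms) / 100.0)

    def gamete_bits() -> np.ndarray:
        """Recombinant transmission bits along the chromosome (Haldane)."""
        bits = np.empty(n, dtype=np.int8)
        bits[0] = rng.integers(0, 2)
        if n > 1:
            bits[1:] = rng.random(n - 1) < thetas
            bits = np.bitwise_xor.accumulate(bits)
        return bits

    hap: dict[str, tuple[np.ndarray, ...]] = {}
    for pid in _topological_order(ped):
        ind = ped.members[pid]
        if ind.is_founder:
            if x and ind.sex == MALE:
                hap[pid] = (np.full(n, slot_ix[(pid, 0)], dtype=np.int16),)
            else:
                hap[pid] = (
                    np.full(n, slot_ix[(pid, 0)], dtype=np.int16),
                    np.full(n, slot_ix[(pid, 1)], dtype=np.int16),
                )
        elif x:
            mo = hap[ind.mother_id]
            bits = gamete_bits()
            mat = np.where(bits == 0, mo[0], mo[-1]).astype(np.int16)
            if ind.sex == MALE:
                hap[pid] = (mat,)
            else:
                fa = hap[ind.father_id]
                hap[pid] = (fa[0].copy(), mat)
        else:
            fa = hap[ind.father_id]
            mo = hap[ind.mother_id]
            bp_ = gamete_bits()
            bm_ = gamete_bits()
            hap[pid] = (
                np.where(bp_ == 0, fa[0], fa[1]).astype(np.int16),
                np.where(bm_ == 0, mo[0], mo[1]).astype(np.int16),
            )

    origins = np.empty((n, len(samples), 2), dtype=np.int16)
    for j, pid in enumerate(samples):
        h = hap[pid]
        origins[:, j, 0] = h[0]
        origins[:, j, 1] = h[-1]
    return origins, slots


def _origins_to_calls(
    ped: Pedigree,
    markers: Sequence[MapMarker],
    origins: np.ndarray,
    slot_alleles: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(calls, phase) from descent plus founder haplotype alleles.

    ``slot_alleles`` is (n_markers, n_slots) of alt indicators.
    """
    samples = sorted(ped.members)
    x = is_x_chrom(markers[0].chrom)
    n = len(markers)
    rows = np.arange(n)[:, None]
    a0 = slot_alleles[rows, origins[:, :, 0]]
    a1 = slot_alleles[rows, origins[:, :, 1]]
    phase = np.stack([a0, a1], axis=2).astype(np.int8)
    calls = (a0 + a1).astype(np.int8)
    if x:
        male_cols = [i for i, s in enumerate(samples) if ped.members[s].sex == MALE]
        # male single X counted diploid: phase holds the same allele twice
        calls[:, male_cols] = (2 * a0[:, male_cols]).astype(np.int8)
    return calls, phase


def gene_drop(
    ped: Pedigree, markers: Sequence[MapMarker], seed
) -> GeneDropResult:
    """Drop founder haplotypes through the pedigree along the genetic map.

    Founder haplotype alleles are Bernoulli(panel_af) per marker; each
    meiosis transmits a Haldane-recombinant gamete (theta from inter-marker
    cM distance, no interference).  On X, fathers pass their single X to
    daughters intact and nothing to sons.
    """
    check_map_sorted(markers)
    rng = _rng(seed)
    samples = sorted(ped.members)
    all_calls = []
    all_phase = []
    all_origins = []
    founder_alleles: dict[str, list[tuple[str, int]]] = {}
    for chrom in dict.fromkeys(m.chrom for m in markers):
        cmarkers = [m for m in markers if m.chrom == chrom]
        origins, slots = _drop_chromosome(ped, cmarkers, rng)
        afs = np.array([m.panel_af for m in cmarkers])
        slot_alleles = (
            rng.random((len(cmarkers), len(slots))) < afs[:, None]
        ).astype(np.int8)
        calls, phase = _origins_to_calls(ped, cmarkers, origins, slot_alleles)
        all_calls.append(calls)
        all_phase.append(phase)
        all_origins.append(origins)
        founder_alleles[chrom] = slots
    table = GenotypeTable(
        [m.marker_id for m in markers],
        samples,
        np.concatenate(all_calls, axis=0),
        phase=np.concatenate(all_phase, axis=0),
    )
    return GeneDropResult(
        table=table,
        origins=np.concatenate(all_origins, axis=0),
        founder_alleles=founder_alleles,
    )


# ---------------------------------------------------------------------------
# causal injection


def _shared_founder(ped: Pedigree, x: bool) -> str:
    """A founder ancestral to every affected member (the variant's origin)."""
    affected = ped.affected_ids()
    common = set.intersection(*(ped.ancestors(a) for a in affected))
    founders = sorted(
        pid
        for pid in common
        if ped.members[pid].is_founder
        and not (x and ped.members[pid].sex == MALE)
    )
    if not founders:
        raise ConfigError(
            f"family {ped.family_id!r}: no shared founder for causal injection"
        )
    return founders[0]


def inject_causal_variant(
    ped: Pedigree,
    markers: Sequence[MapMarker],
    spec: CausalSpec,
    seed,
    *,
    causal_chrom: Optional[str] = None,
    causal_cm: Optional[float] = None,
    control_an: int = 616,
    max_tries: int = 200_000,
) -> tuple[GeneDropResult, VariantRecord]:
    """Gene-drop with a causal variant segregating IBD in all affected.

    The variant is placed on a haplotype of a founder ancestral to all
    affected; the descent of its chromosome is resampled (rejection) until
    every affected member carries it under ``spec.model`` — het: exactly
    one copy each; hom: alternate homozygous (every founder contributes a
    carrier haplotype); xlinked: affected males hemizygous, affected
    females heterozygous.  Returns the accepted drop and the causal exome
    record (damaging effect, zero panel/catalog frequencies, clean quality
    fields, genotypes of every family member implied by descent).
    """
    check_map_sorted(markers)
    rng = _rng(seed)
    chroms = list(dict.fromkeys(m.chrom for m in markers))
    if spec.model == XLINKED:
        if len(ped.affected_ids()) < 2 or not xlinked_compatible(ped):
            raise ConfigError(
                f"family {ped.family_id!r}: affection pattern incompatible "
                "with an X-linked causal model"
            )
        causal_chrom = next((c for c in chroms if is_x_chrom(c)), None)
        if causal_chrom is None:
            raise ConfigError("xlinked causal model but no X markers in map")
    elif causal_chrom is None:
        causal_chrom = chroms[0]
    x = is_x_chrom(causal_chrom)

    cmarkers = [m for m in markers if m.chrom == causal_chrom]
    if causal_cm is None:
        causal_cm = cmarkers[len(cmarkers) // 2].position_cM + 1e-4
    causal_bp = int(causal_cm * BP_PER_CM) + 2
    # virtual locus spliced into the chromosome for a coherent descent
    virt = MapMarker(
        marker_id="__causal__",
        chrom=causal_chrom,
        position_bp=causal_bp,
        position_cM=causal_cm,
        panel_af=0.0,
    )
    aug = sorted(cmarkers + [virt], key=lambda m: m.position_cM)
    vix = aug.index(virt)

    origin_f = _shared_founder(ped, x)
    slots = _founder_slots(ped, x)
    target = slots.index((origin_f, 0))
    affected = ped.affected_ids()
    samples = sorted(ped.members)
    aff_ix = [samples.index(a) for a in affected]

    if spec.model == HOM:
        carrier_slots = {slots.index((f.person_id, 0)) for f in ped.founders}
    else:
        carrier_slots = {target}

    def accepted(origins: np.ndarray) -> bool:
        at = origins[vix]  # (n_samples, 2)
        for j, a in zip(aff_ix, affected):
            o = at[j]
            ind = ped.members[a]
            if spec.model == HET:
                if int(o[0] == target) + int(o[1] == target) != 1:
                    return False
            elif spec.model == HOM:
                if not (o[0] in carrier_slots and o[1] in carrier_slots):
                    return False
            else:  # xlinked
                if ind.sex == MALE:
                    if o[0] != target:
                        return False
                elif int(o[0] == target) + int(o[1] == target) != 1:
                    return False
        return True

    for _ in range(max_tries):
        origins, _ = _drop_chromosome(ped, aug, rng)
        if accepted(origins):
            break
    else:
        raise ConfigError(
            f"causal injection not achieved in {max_tries} tries "
            f"(model {spec.model!r}, family {ped.family_id!r})"
        )

    # drop the remaining chromosomes and assemble the full result
    all_calls, all_phase, all_orig = [], [], []
    founder_alleles: dict[str, list[tuple[str, int]]] = {}
    for chrom in chroms:
        mk = [m for m in markers if m.chrom == chrom]
        if chrom == causal_chrom:
            o_full = origins
            keep = [i for i in range(len(aug)) if i != vix]
            o = o_full[keep]
            sl = _founder_slots(ped, is_x_chrom(chrom))
        else:
            o, sl = _drop_chromosome(ped, mk, rng)
        afs = np.array([m.panel_af for m in mk])
        slot_alleles = (
            rng.random((len(mk), len(sl))) < afs[:, None]
        ).astype(np.int8)
        calls, phase = _origins_to_calls(ped, mk, o, slot_alleles)
        all_calls.append(calls)
        all_phase.append(phase)
        all_orig.append(o)
        founder_alleles[chrom] = sl
    drop = GeneDropResult(
        table=GenotypeTable(
            [m.marker_id for m in markers],
            samples,
            np.concatenate(all_calls, axis=0),
            phase=np.concatenate(all_phase, axis=0),
        ),
        origins=np.concatenate(all_orig, axis=0),
        founder_alleles=founder_alleles,
    )

    # causal genotypes implied by the accepted descent
    at = origins[vix]
    genos: dict[str, int] = {}
    for j, pid in enumerate(samples):
        carried = int(at[j, 0] in carrier_slots) + int(at[j, 1] in carrier_slots)
        if x and ped.members[pid].sex == MALE:
            carried = 2 * int(at[j, 0] in carrier_slots)
        genos[pid] = carried
    depths = {pid: int(30 + rng.poisson(25)) for pid in samples}
    record = VariantRecord(
        chrom=causal_chrom,
        pos=causal_bp,
        ref_allele="C",
        alt_allele="T",
        gene=spec.gene or gene_of(causal_chrom, causal_bp),
        effect=spec.effect,
        dbsnp_known=False,
        panel_afs={p: 0.0 for p in PANELS},
        evs_af=None,
        kg_present=False,
        control_ac=0,
        control_an=control_an,
        genotypes=genos,
        depths=depths,
        vqslod=float(5.0 + 2.0 * rng.random()),
    )
    return drop, record


# ---------------------------------------------------------------------------
# array noise and controls


def simulate_array_genotypes(
    phased: GenotypeTable,
    markers: Sequence[MapMarker],
    error_rate: float,
    missing_rate: float,
    seed,
    ped: Optional[Pedigree] = None,
) -> GenotypeTable:
    """Unphase and perturb gene-dropped genotypes with array noise.

    Each call independently becomes missing with ``missing_rate``; calls
    that remain are hit by a single-allele flip with ``error_rate``
    (0->1, 2->1, 1 -> 0 or 2 with equal odds; hemizygous male X flips
    0<->2).
    """
    if not 0 <= error_rate <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must be in [0,1]")
    rng = _rng(seed)
    calls = phased.calls.copy()
    n_mk, n_s = calls.shape
    x_rows = np.array([is_x_chrom(m.chrom) for m in markers])
    male_cols = np.zeros(n_s, dtype=bool)
    if ped is not None:
        male_cols = np.array(
            [ped.members[s].sex == MALE if s in ped.members else False
             for s in phased.sample_ids]
        )

    miss = rng.random(calls.shape) < missing_rate
    err = (rng.random(calls.shape) < error_rate) & ~miss
    updown = rng.integers(0, 2, size=calls.shape)  # het flip direction

    hemi = x_rows[:, None] & male_cols[None, :]
    new = calls.copy()
    # diploid single-allele flips
    new[err & (calls == 0) & ~hemi] = 1
    new[err & (calls == 2) & ~hemi] = 1
    het = err & (calls == 1) & ~hemi
    new[het] = np.where(updown[het] == 0, 0, 2)
    # hemizygous flips
    new[err & hemi & (calls == 0)] = 2
    new[err & hemi & (calls == 2)] = 0
    new[miss] = MISSING
    return GenotypeTable(phased.marker_ids, phased.sample_ids, new)


def simulate_control_counts(
    af: float, n_samples: int, seed, missing_rate: float = 0.0
) -> tuple[int, int]:
    """Control-cohort alternate-allele count over called chromosomes.

    With ``missing_rate`` = 0 the denominator is exactly 2 x n_samples;
    otherwise whole samples drop out binomially, emulating per-variant
    genotyping missingness.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError("af must be in [0,1]")
    rng = _rng(seed)
    n_called = n_samples - int(rng.binomial(n_samples, missing_rate))
    an = 2 * n_called
    ac = int(rng.binomial(an, af))
    return ac, an


# ---------------------------------------------------------------------------
# exome table


_EFFECT_PROBS = {
    "missense": 0.42,
    "synonymous": 0.33,
    "intronic": 0.15,
    "nonsense": 0.05,
    "splice_site": 0.05,
}


def _single_locus_drop(
    ped: Pedigree, af: np.ndarray, x_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-variant Mendelian genotypes, (n_variants, n_samples)."""
    samples = sorted(ped.members)
    nv = len(af)
    hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid in _topological_order(ped):
        ind = ped.members[pid]
        if ind.is_founder:
            a = (rng.random(nv) < af).astype(np.int8)
            b = (rng.random(nv) < af).astype(np.int8)
            if ind.sex == MALE:
                b = np.where(x_mask, a, b).astype(np.int8)  # single X
            hap[pid] = (a, b)
        else:
            fa = hap[ind.father_id]
            mo = hap[ind.mother_id]
            pat = np.where(rng.integers(0, 2, nv) == 0, fa[0], fa[1])
            mat = np.where(rng.integers(0, 2, nv) == 0, mo[0], mo[1])
            # X: sons take no paternal X (duplicate the maternal allele),
            # daughters take the father's single X
            pat_x = mat if ind.sex == MALE else fa[0]
            pat = np.where(x_mask, pat_x, pat).astype(np.int8)
            hap[pid] = (pat, mat.astype(np.int8))
    out = np.empty((nv, len(samples)), dtype=np.int8)
    for j, pid in enumerate(samples):
        a, b = hap[pid]
        g = a + b
        if ped.members[pid].sex == MALE:
            g = np.where(x_mask, 2 * a, g)
        out[:, j] = g
    return out


def simulate_exome_table(
    ped: Pedigree,
    n_variants: int,
    causal: Sequence[VariantRecord],
    config: SimConfig,
    seed,
) -> AnnotatedVariantSet:
    """Annotated background exome variants plus the injected causal records.

    Background variants carry a mixture of common and rare frequencies,
    realistic catalog membership, binomial control counts over 2 x 308
    chromosomes (with small per-variant missingness, denominators ~604-616),
    depth/VQSLOD fields with configurable failure fractions, and
    Mendelian-consistent genotypes (independent single-locus drops).
    """
    rng = _rng(seed)
    samples = sorted(ped.members)
    chroms = config.chromosomes
    L = config.chrom_length_bp

    ci = rng.integers(0, len(chroms), n_variants)
    pos = rng.integers(1, L + 1, n_variants)
    order = np.lexsort((pos, ci))
    ci, pos = ci[order], pos[order]
    x_mask = np.array([is_x_chrom(chroms[c]) for c in ci])

    effects = rng.choice(
        list(_EFFECT_PROBS), p=list(_EFFECT_PROBS.values()), size=n_variants
    )
    common = rng.random(n_variants) < 0.55
    base_af = np.where(
        common,
        rng.uniform(0.05, 0.5, n_variants),
        rng.uniform(0.0005, 0.02, n_variants),
    )
    panel_noise = rng.normal(1.0, 0.15, (n_variants, len(PANELS)))
    panel_afs = np.clip(base_af[:, None] * panel_noise, 0.0, 0.99)

    known_rare = rng.random(n_variants) < 0.6
    dbsnp = common | known_rare
    kg = common | (known_rare & (rng.random(n_variants) < 0.5))
    evs_present = common | known_rare
    evs_af = np.clip(base_af * rng.normal(1.0, 0.1, n_variants), 0.0, 0.99)

    genos = _single_locus_drop(ped, base_af, x_mask, rng)

    low_dp = rng.random((n_variants, len(samples))) < config.frac_low_depth
    depth = rng.poisson(55, (n_variants, len(samples)))
    depth[low_dp] = rng.integers(0, 4, int(low_dp.sum()))
    fail_vq = rng.random(n_variants) < config.frac_low_vqslod
    vqslod = np.abs(rng.normal(6.0, 2.0, n_variants)) + 0.01
    vqslod[fail_vq] = -rng.uniform(0.0, 6.0, int(fail_vq.sum()))

    miss_u = rng.uniform(0.0, 0.02, n_variants)
    n_called = config.control_cohort_size - rng.binomial(
        config.control_cohort_size, miss_u
    )
    an = 2 * n_called
    ac = rng.binomial(an, base_af)

    ref_alt = [
        tuple(_BASES[b] for b in rng.choice(4, size=2, replace=False))
        for _ in range(n_variants)
    ]

    records: list[VariantRecord] = []
    seen_pos: set[tuple[str, int]] = {(c.chrom, c.pos) for c in causal}
    for i in range(n_variants):
        chrom = chroms[ci[i]]
        key = (chrom, int(pos[i]))
        if key in seen_pos:
            continue
        seen_pos.add(key)
        g_row = genos[i]
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos[i]),
                ref_allele=ref_alt[i][0],
                alt_allele=ref_alt[i][1],
                gene=gene_of(chrom, int(pos[i])),
                effect=str(effects[i]),
                dbsnp_known=bool(dbsnp[i]),
                panel_afs={
                    p: float(panel_afs[i, j]) for j, p in enumerate(PANELS)
                },
                evs_af=float(evs_af[i]) if evs_present[i] else None,
                kg_present=bool(kg[i]),
                control_ac=int(ac[i]),
                control_an=int(an[i]),
                genotypes={s: int(g_row[j]) for j, s in enumerate(samples)},
                depths={s: int(depth[i, j]) for j, s in enumerate(samples)},
                vqslod=float(vqslod[i]),
            )
        )
    records.extend(causal)
    records.sort(key=lambda r: (chroms.index(r.chrom), r.pos))
    return AnnotatedVariantSet(
        records=records, truth={c.variant_id for c in causal}
    )


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class FamilyData:
    """Everything simulated for one family."""

    ped: Pedigree
    array_gt: GenotypeTable  # noisy, unphased
    array_gt_validation: GenotypeTable  # second platform, independent noise
    drop: GeneDropResult  # error-free truth
    exome: AnnotatedVariantSet
    causal_record: VariantRecord


@dataclass
class StudyData:
    config: SimConfig
    markers: list[MapMarker]
    families: list[FamilyData]
    universe: list[str]
    candidate_genes: list[str]


def simulate_family(
    config: SimConfig,
    family_id: str,
    seed,
    markers: Optional[list[MapMarker]] = None,
) -> FamilyData:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_ped, s_inject, s_noise1, s_noise2, s_exome = ss.spawn(5)
    rng = np.random.default_rng(s_ped)
    lo, hi = config.n_affected_range
    tlo, thi = TEMPLATE_CAPACITY[config.pedigree_template]
    n_aff = int(rng.integers(max(lo, tlo), min(hi, thi) + 1))
    ped = generate_pedigree(config.pedigree_template, n_aff, rng)
    ped = Pedigree(
        family_id,
        [replace(m, family_id=family_id) for m in ped.members.values()],
    )
    if markers is None:
        markers = generate_markers(config, np.random.SeedSequence(config.seed))
    drop, causal = inject_causal_variant(
        ped, markers, config.causal_spec, s_inject
    )
    array_gt = simulate_array_genotypes(
        drop.table, markers, config.genotype_error_rate, config.missing_rate,
        s_noise1, ped,
    )
    array_val = simulate_array_genotypes(
        drop.table, markers, config.genotype_error_rate, config.missing_rate,
        s_noise2, ped,
    )
    exome = simulate_exome_table(
        ped, config.n_exome_variants, [causal], config, s_exome
    )
    return FamilyData(
        ped=ped,
        array_gt=array_gt,
        array_gt_validation=array_val,
        drop=drop,
        exome=exome,
        causal_record=causal,
    )


def simulate_study(config: SimConfig) -> StudyData:
    """Simulate the full multi-family study from ``config.seed``.

    The candidate gene list contains every causal gene plus a random tenth
    of the genome's genes, mirroring a literature-derived candidate list
    that includes the true loci among many unrelated ones.
    """
    ss = np.random.SeedSequence(config.seed)
    fam_seeds = ss.spawn(config.n_families + 1)
    markers = generate_markers(config, np.random.SeedSequence(config.seed))
    families = [
        simulate_family(config, f"F{i + 1:03d}", fam_seeds[i], markers)
        for i in range(config.n_families)
    ]
    universe = genes_in_genome(config)
    rng = np.random.default_rng(fam_seeds[-1])
    n_extra = max(1, len(universe) // 10)
    extra = rng.choice(len(universe), size=n_extra, replace=False)
    causal_genes = {f.causal_record.gene for f in families}
    candidates = sorted(causal_genes | {universe[i] for i in extra})
    return StudyData(
        config=config,
        markers=markers,
        families=families,
        universe=universe,
        candidate_genes=candidates,
    )
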