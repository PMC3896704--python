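"""The rare-variant prioritization cascade for one extended family.

Annotated exome variants pass, in order: call-quality gates (VQSLOD,
depth), a damaging-consequence filter (amino-acid-altering or splice-site
changes), rarity gates against three reference panels, an external exome
cohort and an internal control cohort, segregation among all affected
members under an inheritance model (heterozygous, homozygous, or X-linked
hemizygous), and restriction to the family's all-affected IBD segments.
Survivors are summarized per gene across families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .genotypes import MISSING
from .pedigree import Pedigree, xlinked_compatible
from .segments import IBDSegment
from .sharing import is_x_chrom

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "CandidateVariant",
    "GeneSummary",
    "quality_filter",
    "damaging_filter",
    "rarity_filter",
    "rarity_tier",
    "segregation_filter",
    "ibd_restrict",
    "run_family_cascade",
    "summarize_genes",
]

logger = logging.getLogger(__name__)

EFFECTS = ("missense", "nonsense", "splice_site", "synonymous", "intronic", "other")

HET, HOM, XLINKED = "het", "hom", "xlinked"
MODELS = (HET, HOM, XLINKED)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated exome variant with per-sample genotypes.

    ``panel_afs`` maps reference-panel name to alternate-allele frequency;
    ``evs_af`` is None when the variant is absent from the external exome
    cohort; ``control_ac``/``control_an`` count alternate alleles over
    called control chromosomes.  Genotypes are alt-allele dosages in
    {0, 1, 2} with -1 missing (male X uses the diploid {0,2} convention).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    effect: str
    dbsnp_known: bool
    panel_afs: Mapping[str, float]
    evs_af: Optional[float]
    kg_present: bool
    control_ac: int
    control_an: int
    genotypes: Mapping[str, int]
    depths: Mapping[str, int]
    vqslod: float

    def __post_init__(self):
        if not 0 <= self.control_ac <= max(self.control_an, 0):
            raise ValueError(
                f"{self.variant_id}: control counts "
                f"{self.control_ac}/{self.control_an}"
            )
        for name, af in self.panel_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{self.variant_id}: panel {name} af {af}")
        if self.effect not in EFFECTS:
            raise ValueError(f"{self.variant_id}: unknown effect {self.effect!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    @property
    def control_counts(self) -> str:
        """Alternate/total control chromosomes, e.g. ``'15/612'``."""
        return f"{self.control_ac}/{self.control_an}"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the package's standard gates."""

    maf_threshold: float = 0.05  # strict <
    min_depth: int = 4  # inclusive >=
    min_vqslod: float = 0.0  # strict >
    damaging_effects: frozenset = frozenset({"missense", "nonsense", "splice_site"})
    models: tuple = (HET,)
    xlinked_female_hom_ok: bool = False

    def __post_init__(self):
        if self.maf_threshold < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be nonnegative")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")


@dataclass(frozen=True)
class CandidateVariant:
    """A variant surviving the full cascade for one family and model."""

    record: VariantRecord
    family_id: str
    model: str
    rarity: str  # 'novel' | 'rare'
    in_ibd: bool = True
    control_freq_unknown: bool = False


@dataclass
class GeneSummary:
    gene: str
    families_hit: set = field(default_factory=set)
    n_variants_per_family: dict = field(default_factory=dict)
    cis_pair_families: set = field(default_factory=set)

    @property
    def multi_family(self) -> bool:
        return len(self.families_hit) >= 2


# ---------------------------------------------------------------------------
# stages


def quality_filter(
    records: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Drop low-confidence calls.

    Records with VQSLOD <= threshold are removed (strict >); per-sample
    genotypes with depth below ``min_depth`` become missing; records with
    no remaining called genotype are dropped.
    """
    out: list[VariantRecord] = []
    for rec in records:
        if not rec.vqslod > config.min_vqslod:
            continue
        genos = dict(rec.genotypes)
        changed = False
        for sid, g in genos.items():
            if g != MISSING and rec.depths.get(sid, 0) < config.min_depth:
                genos[sid] = MISSING
                changed = True
        if all(g == MISSING for g in genos.values()):
            continue
        out.append(replace(rec, genotypes=genos) if changed else rec)
    return out


def damaging_filter(
    records: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep amino-acid-altering and splice-site variants.

    Splice sites are defined at annotation time (within two nucleotides of
    an exon boundary); here the effect label is trusted.
    """
    out = []
    for rec in records:
        if not rec.effect:
            logger.warning("%s: missing effect annotation, dropped", rec.variant_id)
            continue
        if rec.effect in config.damaging_effects:
            out.append(rec)
    return out


def _maf(freq: float) -> float:
    return min(freq, 1.0 - freq)


def rarity_tier(
    rec: VariantRecord, config: FilterConfig = FilterConfig()
) -> Optional[tuple[str, bool]]:
    """(tier, control_freq_unknown) for a surviving record, else None.

    A record survives when its minor-allele frequency is below the
    threshold in every reference panel, in the external exome cohort, and
    in internal controls.  Survivors are ``novel`` when absent from all
    public catalogs (external exomes, the thousand-genomes flag, dbSNP);
    internal-control counts do not affect novelty.  Zero called control
    chromosomes leave the control frequency unknown: the record is kept
    and flagged.
    """
    t = config.maf_threshold
    for af in rec.panel_afs.values():
        if _maf(af) >= t:
            return None
    if rec.evs_af is not None and _maf(rec.evs_af) >= t:
        return None
    unknown = rec.control_an == 0
    if not unknown and _maf(rec.control_ac / rec.control_an) >= t:
        return None
    novel = rec.evs_af is None and not rec.kg_present and not rec.dbsnp_known
    return ("novel" if novel else "rare", unknown)


def rarity_filter(
    records: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[tuple[VariantRecord, str]]:
    """Survivors with their rarity tier ('novel' or 'rare')."""
    out = []
    for rec in records:
        tier = rarity_tier(rec, config)
        if tier is not None:
            out.append((rec, tier[0]))
    return out


def segregation_filter(
    records: Iterable[VariantRecord],
    ped: Pedigree,
    model: str,
    config: FilterConfig = FilterConfig(),
) -> list[VariantRecord]:
    """Keep variants carried by every affected member under ``model``.

    het: every affected heterozygous; hom: every affected alt/alt;
    xlinked: X-chromosome variants with every affected male hemizygous-alt
    (dosage 2) and every affected female heterozygous (optionally also
    homozygous).  A missing genotype in any affected member fails the
    record — presence in all affected must be observed, not assumed.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    affected = ped.affected_ids()
    if model == XLINKED:
        if len(affected) < 2 or not xlinked_compatible(ped):
            logger.info(
                "family %s: affection pattern not X-linked compatible; "
                "xlinked model yields no candidates",
                ped.family_id,
            )
            return []
    out = []
    for rec in records:
        if model == XLINKED and not is_x_chrom(rec.chrom):
            continue
        ok = True
        for pid in affected:
            g = rec.genotypes.get(pid, MISSING)
            if g == MISSING:
                ok = False
                break
            if model == HET:
                ok = g == 1
            elif model == HOM:
                ok = g == 2
            else:
                if ped.members[pid].sex == "male":
                    ok = g == 2
                else:
                    ok = g == 1 or (config.xlinked_female_hom_ok and g == 2)
            if not ok:
                break
        if ok:
            out.append(rec)
    return out


def ibd_restrict(
    records: Iterable[VariantRecord], segments: Sequence[IBDSegment]
) -> list[VariantRecord]:
    """Keep variants inside any all-affected IBD segment (1-based inclusive)."""
    by_chrom: dict[str, list[IBDSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    out = []
    for rec in records:
        for s in by_chrom.get(rec.chrom, ()):
            if s.start_bp <= rec.pos <= s.end_bp:
                out.append(rec)
                break
    return out


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def run_family_cascade(
    records: Iterable[VariantRecord],
    ped: Pedigree,
    segments: Sequence[IBDSegment],
    config: FilterConfig = FilterConfig(),
) -> list[CandidateVariant]:
    """Full cascade for one family; union over the configured models.

    Output is deterministically ordered by (chromosome, position, model).
    """
    recs = quality_filter(records, config)
    recs = damaging_filter(recs, config)
    tiered = rarity_filter(recs, config)
    tiers = {rec.variant_id: tier for rec, tier in tiered}
    unknown_ctrl = {
        rec.variant_id for rec, _ in tiered if rec.control_an == 0
    }
    rare_recs = [rec for rec, _ in tiered]

    out: list[CandidateVariant] = []
    for model in config.models:
        seg = segregation_filter(rare_recs, ped, model, config)
        for rec in ibd_restrict(seg, segments):
            out.append(
                CandidateVariant(
                    record=rec,
                    family_id=ped.family_id,
                    model=model,
                    rarity=tiers[rec.variant_id],
                    in_ibd=True,
                    control_freq_unknown=rec.variant_id in unknown_ctrl,
                )
            )
    out.sort(key=lambda c: (_chrom_key(c.record.chrom), c.record.pos, c.model))
    return out


def summarize_genes(candidates: Iterable[CandidateVariant]) -> list[GeneSummary]:
    """Aggregate candidates per gene across families.

    ``multi_family`` marks genes hit in at least two distinct families;
    ``cis_pair_families`` lists families contributing two or more distinct
    variants in the gene.  Two heterozygous variants that both segregate in
    all affected members of one family necessarily travel on the same IBD
    haplotype, hence the cis interpretation.
    """
    per_gene: dict[str, dict[str, set]] = {}
    for c in candidates:
        g = per_gene.setdefault(c.record.gene, {})
        g.setdefault(c.family_id, set()).add(c.record.variant_id)
    out = []
    for gene in sorted(per_gene):
        fams = per_gene[gene]
        out.append(
            GeneSummary(
                gene=gene,
                families_hit=set(fams),
                n_variants_per_family={f: len(v) for f, v in fams.items()},
                cis_pair_families={f for f, v in fams.items() if len(v) >= 2},
            )
        )
    return out
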