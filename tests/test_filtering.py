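"""Filter cascade stages, their boundary behavior, stage commutation, and
gene summaries, including the packaged 20-record fixture."""

from pathlib import Path

import pytest

from conftest import DATA, make_cousin_pair
from pedibd.filtering import (
    FilterConfig,
    VariantRecord,
    damaging_filter,
    ibd_restrict,
    quality_filter,
    rarity_filter,
    rarity_tier,
    run_family_cascade,
    segregation_filter,
    summarize_genes,
)
from pedibd.genotypes import MISSING
from pedibd.plink import read_ped
from pedibd.segments import IBDSegment
from pedibd.vcf_io import read_vcf


def make_record(**kw):
    base = dict(
        chrom="1",
        pos=1_500_000,
        ref_allele="C",
        alt_allele="T",
        gene="G1X0014",
        effect="missense",
        dbsnp_known=False,
        panel_afs={"AFR": 0.0, "ASN": 0.0, "EUR": 0.0},
        evs_af=None,
        kg_present=False,
        control_ac=0,
        control_an=604,
        genotypes={"c1": 1, "c2": 1},
        depths={"c1": 50, "c2": 50},
        vqslod=5.0,
    )
    base.update(kw)
    return VariantRecord(**base)


SEGMENT = IBDSegment("CSN", "1", 1_000_000, 2_000_000, 10)


class TestQuality:
    def test_vqslod_zero_dropped(self):
        assert quality_filter([make_record(vqslod=0.0)]) == []

    def test_low_depth_masks_genotype(self):
        rec = make_record(depths={"c1": 3, "c2": 50})
        (out,) = quality_filter([rec])
        assert out.genotypes["c1"] == MISSING
        assert out.genotypes["c2"] == 1

    def test_all_pass_unchanged(self):
        rec = make_record()
        assert quality_filter([rec]) == [rec]


class TestDamaging:
    @pytest.mark.parametrize(
        "effect,kept",
        [
            ("nonsense", True),  # e.g. a Glu->Stop change
            ("missense", True),
            ("splice_site", True),
            ("synonymous", False),
            ("intronic", False),
            ("other", False),
        ],
    )
    def test_effect_classes(self, effect, kept):
        out = damaging_filter([make_record(effect=effect)])
        assert bool(out) == kept


class TestRarity:
    def test_internal_control_rare_tier(self):
        # a known variant at ~2.5% in controls survives as 'rare'
        rec = make_record(
            dbsnp_known=True, control_ac=15, control_an=612,
            panel_afs={"AFR": 0.03, "ASN": 0.01, "EUR": 0.02},
        )
        assert rarity_tier(rec) == ("rare", False)

    def test_panel_maf_boundary_strict(self):
        ok = make_record(panel_afs={"AFR": 0.049, "ASN": 0.0, "EUR": 0.0})
        bad = make_record(panel_afs={"AFR": 0.051, "ASN": 0.0, "EUR": 0.0})
        assert rarity_tier(ok) is not None
        assert rarity_tier(bad) is None

    def test_high_alt_frequency_uses_minor_allele(self):
        # alt at 97%: the minor allele is rare -> record survives
        rec = make_record(panel_afs={"AFR": 0.97, "ASN": 0.98, "EUR": 0.97})
        assert rarity_tier(rec) is not None

    def test_novel_requires_absence_from_public_catalogs_only(self):
        rec = make_record(control_ac=2, control_an=604)  # internal count ok
        assert rarity_tier(rec) == ("novel", False)
        known = make_record(dbsnp_known=True)
        assert rarity_tier(known) == ("rare", False)

    def test_zero_control_chromosomes_kept_with_flag(self):
        rec = make_record(control_ac=0, control_an=0)
        tier, unknown = rarity_tier(rec)
        assert unknown


class TestSegregation:
    def _ped(self):
        return make_cousin_pair()

    def test_het_all_affected_het_kept(self):
        out = segregation_filter([make_record()], self._ped(), "het")
        assert len(out) == 1

    def test_het_one_affected_ref_dropped(self):
        rec = make_record(genotypes={"c1": 1, "c2": 0})
        assert segregation_filter([rec], self._ped(), "het") == []

    def test_missing_affected_genotype_fails(self):
        rec = make_record(genotypes={"c1": 1})
        assert segregation_filter([rec], self._ped(), "het") == []

    def test_hom_model(self):
        rec = make_record(genotypes={"c1": 2, "c2": 2})
        assert len(segregation_filter([rec], self._ped(), "hom")) == 1
        assert segregation_filter([make_record()], self._ped(), "hom") == []

    def test_xlinked_three_generation_fixture(self):
        # affected male cousins hemizygous, sequenced connecting mothers het
        ped = make_cousin_pair(sexes=("male", "male"), linking=("female", "female"))
        rec = make_record(
            chrom="X",
            genotypes={"c1": 2, "c2": 2, "p1": 1, "p2": 1},
        )
        assert len(segregation_filter([rec], ped, "xlinked")) == 1
        # autosomal records never pass the X-linked model
        assert segregation_filter([make_record(genotypes={"c1": 2, "c2": 2})], ped, "xlinked") == []

    def test_xlinked_incompatible_family_yields_nothing(self):
        ped = make_cousin_pair(sexes=("male", "male"), linking=("male", "female"))
        rec = make_record(chrom="X", genotypes={"c1": 2, "c2": 2})
        assert segregation_filter([rec], ped, "xlinked") == []

    def test_unaffected_carriers_tolerated(self):
        # incomplete penetrance: unaffected genotypes are never filtered on
        rec = make_record(genotypes={"c1": 1, "c2": 1, "gf": 1, "sp1": 1})
        assert len(segregation_filter([rec], self._ped(), "het")) == 1


class TestIbdRestrict:
    def test_boundaries_inclusive(self):
        at_start = make_record(pos=1_000_000)
        at_end = make_record(pos=2_000_000)
        past_end = make_record(pos=2_000_001)
        kept = ibd_restrict([at_start, at_end, past_end], [SEGMENT])
        assert kept == [at_start, at_end]

    def test_bruteforce_interval_scan(self):
        import numpy as np

        rng = np.random.default_rng(5)
        segs = [
            IBDSegment("F", "1", 100, 200, 2),
            IBDSegment("F", "1", 500, 800, 3),
            IBDSegment("F", "2", 150, 400, 2),
        ]
        recs = [
            make_record(chrom=str(rng.integers(1, 3)), pos=int(rng.integers(1, 1000)))
            for _ in range(100)
        ]
        kept = ibd_restrict(recs, segs)
        naive = [
            r
            for r in recs
            if any(
                s.chrom == r.chrom and s.start_bp <= r.pos <= s.end_bp
                for s in segs
            )
        ]
        assert kept == naive


class TestStageCommutation:
    def test_damaging_and_rarity_commute(self):
        import numpy as np

        rng = np.random.default_rng(9)
        effects = ["missense", "nonsense", "synonymous", "intronic", "splice_site"]
        recs = []
        for i in range(40):
            af = float(rng.choice([0.0, 0.01, 0.049, 0.1, 0.3]))
            recs.append(
                make_record(
                    pos=1_000_000 + i,
                    effect=str(rng.choice(effects)),
                    panel_afs={"AFR": af, "ASN": af, "EUR": af},
                    dbsnp_known=bool(rng.random() < 0.5),
                )
            )
        a = [r for r, _ in rarity_filter(damaging_filter(recs))]
        b = damaging_filter([r for r, _ in rarity_filter(recs)])
        assert a == b


class TestCascadeFixture:
    def test_packaged_fixture_exact_survivors(self):
        pedigrees, _ = read_ped(DATA / "filter_fixture.ped")
        ped = pedigrees[0]
        records = read_vcf(DATA / "filter_fixture.vcf")
        assert len(records) == 20
        segment = IBDSegment(ped.family_id, "1", 1_000_000, 2_000_000, 10)
        cands = run_family_cascade(records, ped, [segment])
        assert [c.record.pos for c in cands] == [
            1_000_000, 1_100_000, 1_200_000, 1_300_000,
        ]
        assert [c.rarity for c in cands] == ["novel", "rare", "rare", "novel"]
        # idempotence audit: every survivor re-passes each stage predicate
        for c in cands:
            assert quality_filter([c.record]) == [c.record]
            assert damaging_filter([c.record]) == [c.record]
            assert rarity_tier(c.record) is not None
            assert segregation_filter([c.record], ped, "het")
            assert ibd_restrict([c.record], [segment])

    def test_empty_input_empty_output(self):
        ped = make_cousin_pair()
        assert run_family_cascade([], ped, [SEGMENT]) == []


class TestGeneSummaries:
    def _cand(self, gene, family, pos):
        from pedibd.filtering import CandidateVariant

        return CandidateVariant(
            record=make_record(gene=gene, pos=pos),
            family_id=family,
            model="het",
            rarity="rare",
        )

    def test_same_variant_two_families_multi_family(self):
        # one position seen in two families (shared ancestral haplotype)
        cands = [self._cand("SLIT3", "17342", 100), self._cand("SLIT3", "18074", 100)]
        (summary,) = summarize_genes(cands)
        assert summary.multi_family
        assert summary.cis_pair_families == set()

    def test_two_variants_one_family_cis_pair(self):
        cands = [
            self._cand("PRICKLE1", "37232", 100),
            self._cand("PRICKLE1", "37232", 200),
        ]
        (summary,) = summarize_genes(cands)
        assert not summary.multi_family
        assert summary.cis_pair_families == {"37232"}
        assert summary.n_variants_per_family == {"37232": 2}

    def test_single_variant_single_family_neither(self):
        (summary,) = summarize_genes([self._cand("CIC", "F1", 100)])
        assert not summary.multi_family
        assert summary.cis_pair_families == set()

    def test_same_variant_two_models_counted_once(self):
        from pedibd.filtering import CandidateVariant

        rec = make_record(gene="SYN1", chrom="X")
        cands = [
            CandidateVariant(rec, "F1", "het", "rare"),
            CandidateVariant(rec, "F1", "xlinked", "rare"),
        ]
        (summary,) = summarize_genes(cands)
        assert summary.n_variants_per_family == {"F1": 1}
        assert summary.cis_pair_families == set()
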