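"""Synthetic-data generator: determinism, recombination and frequency
calibration, noise rates, causal injection, exome-table structure."""

import numpy as np
import pytest

from pedibd.genotypes import MISSING, mendelian_check
from pedibd.pedigree import MALE
from pedibd.simulate import (
    AnnotatedVariantSet,
    CausalSpec,
    ConfigError,
    SimConfig,
    gene_drop,
    gene_of,
    generate_markers,
    generate_pedigree,
    inject_causal_variant,
    simulate_array_genotypes,
    simulate_control_counts,
    simulate_exome_table,
    simulate_study,
)

SMALL = SimConfig(n_autosomes=1, markers_per_chrom=40, seed=7)


class TestGeneratePedigree:
    def test_cousin_pair_template(self):
        ped = generate_pedigree("cousin_pair", 2, 0)
        assert len(ped) == 8
        affected = ped.affected_ids()
        assert affected == ["c101", "c201"]
        # affected are first cousins: grandparents are shared ancestors
        anc = ped.ancestors("c101") & ped.ancestors("c201")
        assert {"gf", "gm"} <= anc

    def test_over_capacity_is_config_error(self):
        with pytest.raises(ConfigError):
            generate_pedigree("cousin_pair", 5, 0)

    def test_same_seed_same_structure(self):
        a = generate_pedigree("sib_cousins", 4, 123)
        b = generate_pedigree("sib_cousins", 4, 123)
        assert [(m.person_id, m.sex, m.affection) for m in a.members.values()] == [
            (m.person_id, m.sex, m.affection) for m in b.members.values()
        ]

    @pytest.mark.parametrize(
        "template,n", [("sib_cousins", 5), ("avuncular_plus_cousin", 3),
                       ("second_cousin", 2)]
    )
    def test_templates_are_valid_multiplex(self, template, n):
        ped = generate_pedigree(template, n, 11)
        assert ped.validate().ok
        assert len(ped.affected_ids()) == n


class TestGeneDrop:
    def test_zero_distance_markers_cosegregate(self):
        from pedibd.genotypes import MapMarker

        ped = generate_pedigree("cousin_pair", 2, 0)
        markers = [
            MapMarker("a", "1", 100, 0.0, panel_af=0.5),
            MapMarker("b", "1", 200, 0.0, panel_af=0.5),
        ]
        drop = gene_drop(ped, markers, 3)
        # theta=0: the transmitted founder-allele origin is identical
        assert (drop.origins[0] == drop.origins[1]).all()

    def test_haldane_recombinant_fraction_10cM(self):
        from pedibd.genotypes import MapMarker
        from pedibd.pedigree import FEMALE, Individual, Pedigree

        # many independent sib meioses: count recombination between the
        # parents' transmitted origins across 10 cM
        markers = [
            MapMarker("a", "1", 100, 0.0, panel_af=0.5),
            MapMarker("b", "1", 200, 10.0, panel_af=0.5),
        ]
        theta = (1 - np.exp(-0.2)) / 2
        n_kids = 40
        members = [
            Individual("dad", "F", sex=MALE),
            Individual("mom", "F", sex=FEMALE),
        ] + [
            Individual(f"k{i:03d}", "F", "dad", "mom", MALE)
            for i in range(n_kids)
        ]
        ped = Pedigree("F", members)
        rng = np.random.SeedSequence(42).spawn(300)
        rec = tot = 0
        for ss in rng:
            drop = gene_drop(ped, markers, ss)
            kid_ix = [i for i, s in enumerate(sorted(ped.members)) if s.startswith("k")]
            for j in kid_ix:
                for h in (0, 1):
                    tot += 1
                    rec += drop.origins[0, j, h] != drop.origins[1, j, h]
        se = np.sqrt(theta * (1 - theta) / tot)
        assert abs(rec / tot - theta) < 3 * se

    def test_founder_heterozygosity_at_half(self):
        ped = generate_pedigree("cousin_pair", 2, 0)
        cfg = SimConfig(
            n_autosomes=1, markers_per_chrom=400, panel_af_range=(0.5, 0.5), seed=1
        )
        markers = generate_markers(cfg, 2)
        drop = gene_drop(ped, markers, 9)
        founder_cols = [
            i for i, s in enumerate(sorted(ped.members))
            if ped.members[s].is_founder
        ]
        het = (drop.table.calls[:, founder_cols] == 1).mean()
        assert abs(het - 0.5) < 0.05  # 2p(1-p) = 0.5

    def test_gene_dropped_table_is_mendelian(self):
        ped = generate_pedigree("sib_cousins", 4, 3)
        markers = generate_markers(SMALL, 1)
        drop = gene_drop(ped, markers, 4)
        assert mendelian_check(ped, drop.table) == []

    def test_same_seed_bit_identical(self):
        ped = generate_pedigree("cousin_pair", 2, 0)
        markers = generate_markers(SMALL, 1)
        a = gene_drop(ped, markers, 77)
        b = gene_drop(ped, markers, 77)
        assert (a.table.calls == b.table.calls).all()
        assert (a.origins == b.origins).all()


class TestArrayNoise:
    def _drop(self):
        ped = generate_pedigree("cousin_pair", 2, 0)
        cfg = SimConfig(n_autosomes=2, markers_per_chrom=300, seed=3)
        markers = generate_markers(cfg, 2)
        return ped, markers, gene_drop(ped, markers, 5)

    def test_no_noise_is_identity(self):
        ped, markers, drop = self._drop()
        gt = simulate_array_genotypes(drop.table, markers, 0.0, 0.0, 1, ped)
        assert (gt.calls == drop.table.calls).all()
        assert gt.phase is None

    def test_error_rate_calibration(self):
        ped, markers, drop = self._drop()
        gt = simulate_array_genotypes(drop.table, markers, 0.02, 0.0, 1, ped)
        disc = (gt.calls != drop.table.calls).mean()
        n = gt.calls.size
        assert abs(disc - 0.02) < 3 * np.sqrt(0.02 * 0.98 / n)

    def test_missing_rate_calibration(self):
        ped, markers, drop = self._drop()
        gt = simulate_array_genotypes(drop.table, markers, 0.0, 0.05, 1, ped)
        rate = (gt.calls == MISSING).mean()
        n = gt.calls.size
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


class TestCausalInjection:
    def test_het_all_affected_heterozygous_with_linking_parents(self):
        ped = generate_pedigree("cousin_pair", 2, 0)
        markers = generate_markers(SMALL, 1)
        _, causal = inject_causal_variant(ped, markers, CausalSpec(), 13)
        assert causal.genotypes["c101"] == 1
        assert causal.genotypes["c201"] == 1
        assert causal.genotypes["m1"] == 1  # obligate linking parents
        assert causal.genotypes["m2"] == 1
        assert causal.panel_afs == {p: 0.0 for p in causal.panel_afs}
        assert causal.control_ac == 0

    def test_xlinked_impossible_on_father_son(self):
        from conftest import make_trio
        from dataclasses import replace

        trio = make_trio()
        members = [
            replace(m, affection="affected")
            if m.person_id in ("dad", "kid")
            else m
            for m in trio.members.values()
        ]
        from pedibd.pedigree import Pedigree

        ped = Pedigree("TRIO", members)
        cfg = SimConfig(
            n_autosomes=0, markers_per_chrom=20, include_x=True,
            causal_spec=CausalSpec(model="xlinked"), seed=2,
        )
        markers = generate_markers(cfg, 4)
        with pytest.raises(ConfigError):
            inject_causal_variant(ped, markers, CausalSpec(model="xlinked"), 1)

    def test_het_variant_lies_in_true_shared_descent(self):
        # brute-force descent check over replicates: every affected carries
        # the injected founder haplotype at the causal locus
        ped = generate_pedigree("cousin_pair", 2, 0)
        markers = generate_markers(SMALL, 1)
        for seed in range(20):
            _, causal = inject_causal_variant(ped, markers, CausalSpec(), seed)
            for aff in ped.affected_ids():
                assert causal.genotypes[aff] == 1

    def test_hom_model_makes_affected_homozygous(self):
        ped = generate_pedigree("cousin_pair", 2, 0)
        markers = generate_markers(SMALL, 1)
        _, causal = inject_causal_variant(
            ped, markers, CausalSpec(model="hom"), 3
        )
        assert all(causal.genotypes[a] == 2 for a in ped.affected_ids())

    def test_xlinked_model_hemizygous_males(self):
        cfg = SimConfig(
            n_autosomes=1, markers_per_chrom=40, include_x=True,
            causal_spec=CausalSpec(model="xlinked"), seed=2,
        )
        ped = generate_pedigree("cousin_pair", 2, 0)  # male cousins, sister mothers
        markers = generate_markers(cfg, 4)
        _, causal = inject_causal_variant(
            ped, markers, CausalSpec(model="xlinked"), 5
        )
        assert causal.chrom == "X"
        for a in ped.affected_ids():
            expect = 2 if ped.members[a].sex == MALE else 1
            assert causal.genotypes[a] == expect


class TestControlsAndExome:
    def test_zero_frequency_gives_zero_count(self):
        ac, an = simulate_control_counts(0.0, 308, 1)
        assert (ac, an) == (0, 616)

    def test_cohort_chromosome_count(self):
        _, an = simulate_control_counts(0.1, 308, 1)
        assert an == 616

    def test_binomial_calibration(self):
        counts = [simulate_control_counts(0.5, 500, s)[0] for s in range(200)]
        frac = np.mean(counts) / 1000
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / (1000 * 200))

    def _exome(self, n=2000):
        ped = generate_pedigree("cousin_pair", 2, 0)
        cfg = SimConfig(n_autosomes=2, markers_per_chrom=50, n_exome_variants=n, seed=5)
        markers = generate_markers(cfg, 1)
        _, causal = inject_causal_variant(ped, markers, CausalSpec(), 3)
        return ped, cfg, simulate_exome_table(ped, n, [causal], cfg, 9)

    def test_causal_in_records_and_truth(self):
        _, _, varset = self._exome(500)
        assert len(varset.truth) == 1
        vid = next(iter(varset.truth))
        assert any(r.variant_id == vid for r in varset.records)

    def test_background_is_mendelian(self):
        from pedibd.genotypes import GenotypeTable

        ped, _, varset = self._exome(500)
        samples = sorted(ped.members)
        autosomal = [r for r in varset.records if r.chrom != "X"]
        calls = np.array(
            [[r.genotypes[s] for s in samples] for r in autosomal], dtype=np.int8
        )
        gt = GenotypeTable(
            [r.variant_id for r in autosomal], samples, calls
        )
        assert mendelian_check(ped, gt) == []

    def test_vqslod_failure_fraction(self):
        _, cfg, varset = self._exome(4000)
        frac = np.mean([r.vqslod <= 0 for r in varset.records])
        n = len(varset.records)
        assert abs(frac - cfg.frac_low_vqslod) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_control_denominators_in_study_range(self):
        _, _, varset = self._exome(500)
        ans = [r.control_an for r in varset.records]
        assert min(ans) >= 580 and max(ans) <= 616

    def test_gene_assignment_consistent(self):
        _, _, varset = self._exome(200)
        for r in varset.records:
            assert r.gene == gene_of(r.chrom, r.pos)


class TestStudyDeterminism:
    def test_same_seed_same_study(self):
        cfg = SimConfig(
            n_families=2, n_autosomes=1, markers_per_chrom=30,
            n_exome_variants=100, seed=21,
        )
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        for fa, fb in zip(a.families, b.families):
            assert (fa.array_gt.calls == fb.array_gt.calls).all()
            assert [r.variant_id for r in fa.exome.records] == [
                r.variant_id for r in fb.exome.records
            ]
        assert a.candidate_genes == b.candidate_genes

    def test_xlinked_requires_x(self):
        with pytest.raises(ConfigError):
            SimConfig(causal_spec=CausalSpec(model="xlinked"), include_x=False)
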