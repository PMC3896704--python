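"""VCF v4.2 subset I/O for annotated exome records, plus TSV outputs.

INFO keys: GENE, EFF, AF_PANEL1/2/3 (three reference panels), EVS_AF
(absent when the variant is missing from the external exome cohort), KG
and DBSNP flags, AC_CTRL/AN_CTRL internal-control counts, VQSLOD.
Per-sample FORMAT is GT:DP.  Reading goes through cyvcf2.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .filtering import CandidateVariant, GeneSummary, VariantRecord
from .genotypes import MISSING
from .simulate import PANELS, AnnotatedVariantSet

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_truth",
    "read_truth",
    "write_candidates_tsv",
    "write_gene_summary_tsv",
]

_HEADER = """\
##fileformat=VCFv4.2
##source=pedibd
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">
##INFO=<ID=AF_PANEL1,Number=1,Type=Float,Description="Alt AF, reference panel 1">
##INFO=<ID=AF_PANEL2,Number=1,Type=Float,Description="Alt AF, reference panel 2">
##INFO=<ID=AF_PANEL3,Number=1,Type=Float,Description="Alt AF, reference panel 3">
##INFO=<ID=EVS_AF,Number=1,Type=Float,Description="External exome cohort AF">
##INFO=<ID=KG,Number=0,Type=Flag,Description="Present in thousand-genomes catalog">
##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Known dbSNP site">
##INFO=<ID=AC_CTRL,Number=1,Type=Integer,Description="Control alt allele count">
##INFO=<ID=AN_CTRL,Number=1,Type=Integer,Description="Control called chromosomes">
##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="Variant quality log-odds">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_OUT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, varset: AnnotatedVariantSet, samples: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for chrom in dict.fromkeys(r.chrom for r in varset.records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in varset.records:
            info = [
                f"GENE={rec.gene}",
                f"EFF={rec.effect}",
            ]
            for i, p in enumerate(PANELS):
                info.append(f"AF_PANEL{i + 1}={rec.panel_afs[p]:.6g}")
            if rec.evs_af is not None:
                info.append(f"EVS_AF={rec.evs_af:.6g}")
            if rec.kg_present:
                info.append("KG")
            if rec.dbsnp_known:
                info.append("DBSNP")
            info.append(f"AC_CTRL={rec.control_ac}")
            info.append(f"AN_CTRL={rec.control_an}")
            info.append(f"VQSLOD={rec.vqslod:.4g}")
            cols = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref_allele,
                rec.alt_allele,
                ".",
                "PASS",
                ";".join(info),
                "GT:DP",
            ]
            for s in samples:
                g = rec.genotypes.get(s, MISSING)
                d = rec.depths.get(s, 0)
                cols.append(f"{_GT_OUT[g]}:{d}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path) -> list[VariantRecord]:
    """Parse an annotated exome VCF into :class:`VariantRecord` objects."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for v in vcf:
        dosage: dict[str, int] = {}
        for s, g in zip(samples, v.genotypes):
            a = [x for x in g[:-1] if x >= 0]
            dosage[s] = sum(a) if len(a) == 2 else MISSING
        dp = v.format("DP")
        depths = {
            s: int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else 0
            for i, s in enumerate(samples)
        }
        evs = v.INFO.get("EVS_AF")
        out.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                gene=v.INFO.get("GENE"),
                effect=v.INFO.get("EFF"),
                dbsnp_known=bool(v.INFO.get("DBSNP")),
                panel_afs={
                    p: float(v.INFO.get(f"AF_PANEL{i + 1}"))
                    for i, p in enumerate(PANELS)
                },
                evs_af=float(evs) if evs is not None else None,
                kg_present=bool(v.INFO.get("KG")),
                control_ac=int(v.INFO.get("AC_CTRL")),
                control_an=int(v.INFO.get("AN_CTRL")),
                genotypes=dosage,
                depths=depths,
                vqslod=float(v.INFO.get("VQSLOD")),
            )
        )
    vcf.close()
    return out


def write_truth(path, varset: AnnotatedVariantSet) -> None:
    """Truth manifest: one injected causal variant id per line."""
    with open(path, "w") as fh:
        fh.write("variant_id\tgene\n")
        by_id = {r.variant_id: r for r in varset.records}
        for vid in sorted(varset.truth):
            fh.write(f"{vid}\t{by_id[vid].gene}\n")


def read_truth(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            vid, gene = line.split()
            out[vid] = gene
    return out


def write_candidates_tsv(path, candidates: Iterable[CandidateVariant]) -> None:
    cols = [
        "family",
        "chrom",
        "pos",
        "ref",
        "alt",
        "gene",
        "effect",
        "model",
        "rarity",
        "control_counts",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            r = c.record
            fh.write(
                "\t".join(
                    [
                        c.family_id,
                        r.chrom,
                        str(r.pos),
                        r.ref_allele,
                        r.alt_allele,
                        r.gene,
                        r.effect,
                        c.model,
                        c.rarity,
                        r.control_counts,
                    ]
                )
                + "\n"
            )


def write_gene_summary_tsv(path, summaries: Iterable[GeneSummary]) -> None:
    cols = [
        "gene",
        "n_families",
        "families",
        "multi_family",
        "cis_pair_families",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.gene,
                        str(len(s.families_hit)),
                        ",".join(sorted(s.families_hit)),
                        str(int(s.multi_family)),
                        ",".join(sorted(s.cis_pair_families)) or "-",
                    ]
                )
                + "\n"
            )
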