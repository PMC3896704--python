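"""Study-level orchestration: simulate -> IBD -> filter -> summarize -> enrich.

``run_all`` executes the per-family pipeline over a declarative
:class:`RunConfig` (loadable from YAML) and writes segments (BED + TSV),
sharing profiles, candidate variants, gene summaries, enrichment JSON, a QC
report and a manifest with per-stage record counts (the filtering funnel).
Outputs are deterministic byte-for-byte given config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .concordance import call_rate_qc, genotype_concordance
from .enrichment import enrichment
from .filtering import (
    FilterConfig,
    damaging_filter,
    ibd_restrict,
    quality_filter,
    rarity_filter,
    run_family_cascade,
    segregation_filter,
    summarize_genes,
)
from .genotypes import GenotypeTable
from .ld import PruneParams
from .model import FamilyIBDModel
from .plink import read_map, read_ped, write_freq, write_map, write_ped
from .segments import SegmentParams, write_segments_bed
from .simulate import ConfigError, StudyData
from .vcf_io import (
    read_vcf,
    write_candidates_tsv,
    write_gene_summary_tsv,
    write_truth,
    write_vcf,
)

__all__ = ["FamilyInput", "RunConfig", "run_all", "write_study"]


@dataclass
class FamilyInput:
    family_id: str
    ped: Path
    vcf: Path
    validation_ped: Optional[Path] = None


@dataclass
class RunConfig:
    """Declarative inputs and parameters for ``run_all``.

    ``prune`` defaults to None: windowed LD pruning estimates r2 from a
    *population* reference panel, and applying it to a handful of relatives
    would prune away the very descent correlation the sharing model
    measures.  Enable it (a ``prune:`` section in the YAML) only when the
    PED samples are an unrelated reference cohort.
    """

    map_path: Path
    freq_path: Optional[Path]
    families: list[FamilyInput]
    candidate_genes: Optional[Path] = None
    universe: Optional[Path] = None
    prune: Optional[PruneParams] = None
    segments: SegmentParams = field(default_factory=SegmentParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    genotype_error: float = 0.01
    max_meioses: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def p(key, sub=None) -> Optional[Path]:
            val = raw.get(key) if sub is None else sub.get(key)
            return (base / val) if val else None

        fams = [
            FamilyInput(
                family_id=f["id"],
                ped=base / f["ped"],
                vcf=base / f["vcf"],
                validation_ped=(
                    base / f["validation_ped"] if f.get("validation_ped") else None
                ),
            )
            for f in raw.get("families", [])
        ]
        filt = dict(raw.get("filter", {}))
        if "models" in filt:
            filt["models"] = tuple(filt["models"])
        if "damaging_effects" in filt:
            filt["damaging_effects"] = frozenset(filt["damaging_effects"])
        return cls(
            map_path=p("map"),
            freq_path=p("freq"),
            families=fams,
            candidate_genes=p("candidate_genes"),
            universe=p("universe"),
            prune=PruneParams(**raw["prune"]) if "prune" in raw else None,
            segments=SegmentParams(**raw.get("segments", {})),
            filter=FilterConfig(**filt),
            genotype_error=float(raw.get("genotype_error", 0.01)),
            max_meioses=int(raw.get("max_meioses", 20)),
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        missing = []
        for path in [self.map_path, self.freq_path, self.candidate_genes, self.universe]:
            if path is not None and not Path(path).exists():
                missing.append(str(path))
        for f in self.families:
            for path in (f.ped, f.vcf, f.validation_ped):
                if path is not None and not Path(path).exists():
                    missing.append(str(path))
        if missing:
            raise ConfigError(f"missing input paths: {missing}")
        if not self.families:
            raise ConfigError("no families configured")


def _read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns (and writes) the manifest."""
    config.validate_paths()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    markers = read_map(config.map_path, config.freq_path)

    all_candidates = []
    all_segments = []
    summaries = []
    sharing_rows = []
    qc: dict = {"call_rate": {}, "concordance": {}}
    funnel: dict = {}

    for fam in config.families:
        pedigrees, gt = read_ped(fam.ped, markers)
        ped = next(p for p in pedigrees if p.family_id == fam.family_id)
        if gt is None:
            raise ConfigError(f"{fam.ped}: no genotype columns")

        qc["call_rate"][fam.family_id] = {
            s: passed for s, passed in call_rate_qc(gt).items()
        }
        if fam.validation_ped is not None:
            _, gt_val = read_ped(fam.validation_ped, markers)
            report = genotype_concordance(gt, gt_val, markers, markers)
            qc["concordance"][fam.family_id] = {
                "overall_mean": report.overall_mean,
                "n_sites": report.n_sites_compared,
            }

        results = FamilyIBDModel(
            ped,
            gt,
            markers,
            prune_params=config.prune,
            genotype_error=config.genotype_error,
            max_meioses=config.max_meioses,
        ).fit()
        segs = results.call_segments(config.segments)
        all_segments.extend(segs)
        summaries.append(results.summary(config.segments))
        frame = results.sharing_frame()
        sharing_rows.append(frame)

        records = read_vcf(fam.vcf)
        n0 = len(records)
        q = quality_filter(records, config.filter)
        d = damaging_filter(q, config.filter)
        tiers = rarity_filter(d, config.filter)
        rare = [r for r, _ in tiers]
        per_model = {}
        for m in config.filter.models:
            seg_recs = segregation_filter(rare, ped, m, config.filter)
            per_model[m] = {
                "segregating": len(seg_recs),
                "in_ibd": len(ibd_restrict(seg_recs, segs)),
            }
        cands = run_family_cascade(records, ped, segs, config.filter)
        all_candidates.extend(cands)
        funnel[fam.family_id] = {
            "input": n0,
            "quality": len(q),
            "damaging": len(d),
            "rare_or_novel": len(rare),
            "models": per_model,
            "candidates": len(cands),
            "n_segments": len(segs),
        }

    # outputs
    import pandas as pd

    write_segments_bed(outdir / "segments.bed", all_segments)
    pd.concat(summaries, ignore_index=True).to_csv(
        outdir / "segments_summary.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    pd.concat(sharing_rows, ignore_index=True).to_csv(
        outdir / "sharing.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_candidates_tsv(outdir / "candidates.tsv", all_candidates)
    gene_summaries = summarize_genes(all_candidates)
    write_gene_summary_tsv(outdir / "gene_summary.tsv", gene_summaries)

    enrich_dict = None
    if config.candidate_genes is not None and config.universe is not None:
        hit_genes = {c.record.gene for c in all_candidates}
        if hit_genes:
            result = enrichment(
                hit_genes,
                _read_gene_list(config.candidate_genes),
                _read_gene_list(config.universe),
            )
            enrich_dict = result.to_dict()
            with open(outdir / "enrichment.json", "w") as fh:
                json.dump(enrich_dict, fh, indent=2, sort_keys=True)

    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_families": len(config.families),
        "funnel": funnel,
        "n_candidates": len(all_candidates),
        "n_genes_hit": len({c.record.gene for c in all_candidates}),
        "n_multi_family_genes": sum(1 for g in gene_summaries if g.multi_family),
        "n_cis_pair_genes": sum(
            1 for g in gene_summaries if g.cis_pair_families
        ),
        "enrichment": enrich_dict,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_study(study: StudyData, outdir) -> Path:
    """Write a simulated study as PED/MAP/VCF inputs plus a run-all YAML.

    Returns the path of the written config file.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(outdir / "markers.map", study.markers)
    write_freq(outdir / "markers.freq", study.markers)
    with open(outdir / "universe.txt", "w") as fh:
        fh.write("\n".join(study.universe) + "\n")
    with open(outdir / "candidate_genes.txt", "w") as fh:
        fh.write("\n".join(study.candidate_genes) + "\n")

    fam_entries = []
    for fam in study.families:
        fid = fam.ped.family_id
        write_ped(outdir / f"{fid}.ped", [fam.ped], fam.array_gt, study.markers)
        write_ped(
            outdir / f"{fid}.validation.ped",
            [fam.ped],
            fam.array_gt_validation,
            study.markers,
        )
        write_vcf(outdir / f"{fid}.vcf", fam.exome, sorted(fam.ped.members))
        write_truth(outdir / f"{fid}.truth.tsv", fam.exome)
        fam_entries.append(
            {
                "id": fid,
                "ped": f"{fid}.ped",
                "validation_ped": f"{fid}.validation.ped",
                "vcf": f"{fid}.vcf",
            }
        )

    models = [study.config.causal_spec.model]
    cfg = {
        "map": "markers.map",
        "freq": "markers.freq",
        "candidate_genes": "candidate_genes.txt",
        "universe": "universe.txt",
        "families": fam_entries,
        "filter": {"models": models},
        "seed": study.config.seed,
    }
    cfg_path = outdir / "study.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
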