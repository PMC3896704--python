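"""Family-level IBD model: data in, fitted sharing profiles and segments out.

:class:`FamilyIBDModel` bundles one family's pedigree, array genotypes and
genetic map; ``fit()`` LD-prunes each chromosome, runs the
inheritance-vector HMM, and returns :class:`FamilyIBDResults` carrying the
per-chromosome sharing profiles, segment calls, and a summary table.
Autosomes are always analyzed; the X chromosome only when the affection
pattern is compatible with X-linked inheritance.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, MapMarker
from .ld import PruneParams, ld_prune
from .pedigree import Pedigree, xlinked_compatible
from .segments import IBDSegment, SegmentParams, call_segments
from .sharing import SharingProfile, compute_sharing, is_x_chrom

__all__ = ["FamilyIBDModel", "FamilyIBDResults", "segments_genomewide"]


class FamilyIBDModel:
    """Multipoint all-affected IBD sharing model for one family.

    Parameters
    ----------
    ped, gt, markers
        Pedigree, genotype table and map-ordered markers (all chromosomes).
    prune_params
        LD pruning applied per chromosome before the HMM; ``None`` disables
        pruning (markers assumed pre-pruned).
    genotype_error
        Optional per-genotype error term in the emission model (robustness
        against array miscalls); 0 disables it.
    """

    def __init__(
        self,
        ped: Pedigree,
        gt: GenotypeTable,
        markers: Sequence[MapMarker],
        prune_params: Optional[PruneParams] = PruneParams(),
        genotype_error: float = 0.0,
        max_meioses: int = 20,
    ):
        if [m.marker_id for m in markers] != gt.marker_ids:
            raise ValueError("marker list does not match genotype table")
        self.ped = ped
        self.gt = gt
        self.markers = list(markers)
        self.prune_params = prune_params
        self.genotype_error = genotype_error
        self.max_meioses = max_meioses

    @classmethod
    def from_plink(
        cls, ped_path, map_path, freq_path=None, family_id=None, **kwargs
    ) -> "FamilyIBDModel":
        from .plink import read_map, read_ped

        markers = read_map(map_path, freq_path)
        pedigrees, gt = read_ped(ped_path, markers)
        if gt is None:
            raise ValueError(f"{ped_path}: no genotype columns")
        if family_id is None:
            if len(pedigrees) != 1:
                raise ValueError("several families present; pass family_id")
            ped = pedigrees[0]
        else:
            ped = next(p for p in pedigrees if p.family_id == family_id)
        cols = [i for i, s in enumerate(gt.sample_ids) if s in ped]
        fam_gt = GenotypeTable(
            gt.marker_ids,
            [gt.sample_ids[i] for i in cols],
            gt.calls[:, cols],
        )
        return cls(ped, fam_gt, markers, **kwargs)

    def _chromosomes(self) -> list[str]:
        seen: list[str] = []
        for m in self.markers:
            if m.chrom not in seen:
                seen.append(m.chrom)
        return seen

    def fit(self) -> "FamilyIBDResults":
        profiles: dict[str, SharingProfile] = {}
        retained: dict[str, list[str]] = {}
        x_ok = None
        for chrom in self._chromosomes():
            if is_x_chrom(chrom):
                if x_ok is None:
                    x_ok = (
                        len(self.ped.affected_ids()) >= 2
                        and xlinked_compatible(self.ped)
                    )
                if not x_ok:
                    continue
            cmarkers = [m for m in self.markers if m.chrom == chrom]
            cgt = self.gt.subset_markers([m.marker_id for m in cmarkers])
            if self.prune_params is not None:
                keep = ld_prune(cgt, cmarkers, self.prune_params)
                cmarkers = [m for m in cmarkers if m.marker_id in set(keep)]
                cgt = cgt.subset_markers(keep)
            retained[chrom] = [m.marker_id for m in cmarkers]
            if not cmarkers:
                continue
            profiles[chrom] = compute_sharing(
                self.ped,
                cgt,
                cmarkers,
                genotype_error=self.genotype_error,
                max_meioses=self.max_meioses,
            )
        return FamilyIBDResults(self, profiles, retained, x_analyzed=bool(x_ok))


class FamilyIBDResults:
    """Fitted sharing profiles for one family, with segment calling on top."""

    def __init__(
        self,
        model: FamilyIBDModel,
        profiles: dict[str, SharingProfile],
        retained_markers: dict[str, list[str]],
        x_analyzed: bool,
    ):
        self.model = model
        self.profiles = profiles
        self.retained_markers = retained_markers
        self.x_analyzed = x_analyzed

    @property
    def family_id(self) -> str:
        return self.model.ped.family_id

    def call_segments(
        self, params: SegmentParams = SegmentParams()
    ) -> list[IBDSegment]:
        out: list[IBDSegment] = []
        for chrom, profile in self.profiles.items():
            cmarkers = [m for m in self.model.markers if m.chrom == chrom]
            out.extend(call_segments(profile, cmarkers, params))
        return out

    def summary(self, seg_params: SegmentParams = SegmentParams()) -> pd.DataFrame:
        """Per-chromosome marker counts, mean sharing and segment totals."""
        rows = []
        for chrom, profile in self.profiles.items():
            segs = [s for s in self.call_segments(seg_params) if s.chrom == chrom]
            rows.append(
                {
                    "family_id": self.family_id,
                    "chrom": chrom,
                    "n_markers": len(profile.marker_ids),
                    "mean_sharing": float(np.mean(profile.sharing)),
                    "n_segments": len(segs),
                    "segment_bp": int(
                        sum(s.end_bp - s.start_bp + 1 for s in segs)
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "family_id",
                "chrom",
                "n_markers",
                "mean_sharing",
                "n_segments",
                "segment_bp",
            ],
        )

    def sharing_frame(self) -> pd.DataFrame:
        """Long-format sharing profile across chromosomes."""
        rows = []
        pos = {m.marker_id: m.position_bp for m in self.model.markers}
        for chrom, profile in self.profiles.items():
            for mid, s in zip(profile.marker_ids, profile.sharing):
                rows.append(
                    {
                        "family_id": self.family_id,
                        "chrom": chrom,
                        "marker_id": mid,
                        "position_bp": pos[mid],
                        "sharing": s,
                    }
                )
        return pd.DataFrame(
            rows, columns=["family_id", "chrom", "marker_id", "position_bp", "sharing"]
        )

    def plot_sharing(self, chrom: str, ax=None, seg_params: SegmentParams = SegmentParams()):
        """Sharing profile along one chromosome with called segments shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        profile = self.profiles[chrom]
        pos = {m.marker_id: m.position_bp for m in self.model.markers}
        x = [pos[mid] / 1e6 for mid in profile.marker_ids]
        ax.plot(x, profile.sharing, lw=1)
        ax.axhline(seg_params.sharing_threshold, ls="--", c="grey", lw=0.8)
        for s in self.call_segments(seg_params):
            if s.chrom == chrom:
                ax.axvspan(s.start_bp / 1e6, s.end_bp / 1e6, alpha=0.2)
        ax.set_xlabel(f"chr{chrom} position (Mb)")
        ax.set_ylabel("P(all affected IBD)")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(f"family {self.family_id}")
        return ax


def segments_genomewide(
    ped: Pedigree,
    gt: GenotypeTable,
    markers: Sequence[MapMarker],
    prune_params: Optional[PruneParams] = PruneParams(),
    seg_params: SegmentParams = SegmentParams(),
    **model_kwargs,
) -> list[IBDSegment]:
    """Compose LD pruning, sharing HMM and segment calling per chromosome."""
    if not markers:
        return []
    model = FamilyIBDModel(ped, gt, markers, prune_params, **model_kwargs)
    return model.fit().call_segments(seg_params)
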