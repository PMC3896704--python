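"""PLINK-style text formats: 6-column PED pedigree block, MAP, and
allele-frequency sidecar.

PED columns: family, person, father, mother, sex (1=male, 2=female),
phenotype (1=unaffected, 2=affected, 0/-9=unknown); ``0`` means a missing
parent.  Optional genotype columns follow as allele pairs (``0 0`` =
missing).  MAP columns: chrom, marker id, cM, bp.  Because MAP carries no
allele frequencies, a sidecar TSV (marker id, ref, alt, panel alt-allele
frequency) round-trips the panel frequencies the sharing model needs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable, MapMarker
from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    UNKNOWN,
    Individual,
    Pedigree,
)

__all__ = [
    "read_ped",
    "write_ped",
    "read_map",
    "write_map",
    "read_freq",
    "write_freq",
]

_SEX_OUT = {MALE: "1", FEMALE: "2"}
_SEX_IN = {"1": MALE, "2": FEMALE}
_PHENO_OUT = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}
_PHENO_IN = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


def write_map(path, markers: Sequence[MapMarker]) -> None:
    with open(path, "w") as fh:
        for m in markers:
            fh.write(
                f"{m.chrom}\t{m.marker_id}\t{m.position_cM:g}\t{m.position_bp}\n"
            )


def write_freq(path, markers: Sequence[MapMarker]) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tref\talt\tpanel_af\n")
        for m in markers:
            fh.write(
                f"{m.marker_id}\t{m.ref_allele}\t{m.alt_allele}\t{m.panel_af:.6g}\n"
            )


def read_freq(path) -> dict[str, tuple[str, str, float]]:
    out: dict[str, tuple[str, str, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker_id"):
            raise ValueError(f"{path}: missing frequency header")
        for line in fh:
            mid, ref, alt, af = line.split()
            out[mid] = (ref, alt, float(af))
    return out


def read_map(map_path, freq_path=None) -> list[MapMarker]:
    freqs = read_freq(freq_path) if freq_path is not None else {}
    markers: list[MapMarker] = []
    with open(map_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, mid, cm, bp = line.split()
            ref, alt, af = freqs.get(mid, ("A", "G", 0.5))
            markers.append(
                MapMarker(
                    marker_id=mid,
                    chrom=chrom,
                    position_bp=int(bp),
                    position_cM=float(cm),
                    ref_allele=ref,
                    alt_allele=alt,
                    panel_af=af,
                )
            )
    return markers


def write_ped(
    path,
    pedigrees: Sequence[Pedigree],
    gt: Optional[GenotypeTable] = None,
    markers: Optional[Sequence[MapMarker]] = None,
) -> None:
    """Write one or more families; genotype columns appear when ``gt`` is given."""
    if gt is not None and markers is not None:
        if [m.marker_id for m in markers] != gt.marker_ids:
            raise ValueError("marker list does not match genotype table")
    with open(path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members.values():
                fields = [
                    ind.family_id,
                    ind.person_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_OUT[ind.sex],
                    _PHENO_OUT[ind.affection],
                ]
                if gt is not None and ind.person_id in gt.sample_ids:
                    col = gt.column(ind.person_id)
                    for j, g in enumerate(col):
                        if markers is not None:
                            ref, alt = markers[j].ref_allele, markers[j].alt_allele
                        else:
                            ref, alt = "A", "B"
                        if g == MISSING:
                            fields += ["0", "0"]
                        elif g == 0:
                            fields += [ref, ref]
                        elif g == 1:
                            fields += [ref, alt]
                        else:
                            fields += [alt, alt]
                fh.write(" ".join(fields) + "\n")


def read_ped(
    path, markers: Optional[Sequence[MapMarker]] = None
) -> tuple[list[Pedigree], Optional[GenotypeTable]]:
    """Read a PED file into pedigrees and, when genotype columns are
    present and ``markers`` supplied, a :class:`GenotypeTable`.

    Returns pedigrees in file order; the genotype table (or None) covers all
    samples across families in file order.
    """
    fam_members: dict[str, list[Individual]] = {}
    sample_ids: list[str] = []
    geno_rows: list[list[int]] = []
    have_genos = False
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fam, pid, fid, mid, sex, pheno = parts[:6]
            rest = parts[6:]
            ind = Individual(
                person_id=pid,
                family_id=fam,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_IN.get(sex, MALE),
                affection=_PHENO_IN.get(pheno, UNKNOWN),
            )
            fam_members.setdefault(fam, []).append(ind)
            sample_ids.append(pid)
            if rest:
                have_genos = True
                if markers is None:
                    raise ValueError(
                        "PED has genotype columns but no marker list was given"
                    )
                if len(rest) != 2 * len(markers):
                    raise ValueError(
                        f"sample {pid}: {len(rest)} allele fields, "
                        f"expected {2 * len(markers)}"
                    )
                row = []
                for j in range(len(markers)):
                    a, b = rest[2 * j], rest[2 * j + 1]
                    if a == "0" or b == "0":
                        row.append(MISSING)
                    else:
                        alt = markers[j].alt_allele
                        row.append(int(a == alt) + int(b == alt))
                geno_rows.append(row)

    pedigrees = [Pedigree(fam, members) for fam, members in fam_members.items()]
    table = None
    if have_genos:
        calls = np.array(geno_rows, dtype=np.int8).T  # (markers, samples)
        table = GenotypeTable([m.marker_id for m in markers], sample_ids, calls)
    return pedigrees, table
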