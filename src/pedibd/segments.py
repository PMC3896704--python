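"""Sliding-window IBD segment calling from per-marker sharing profiles.

A marker qualifies when it sits inside some window of ``window_markers``
consecutive markers whose sharing all exceeds the threshold (strictly).
That is equivalent to lying in a maximal above-threshold run of length at
least ``window_markers``.  Chromosomes with fewer markers than the window
qualify only when every marker exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import MapMarker

__all__ = ["SegmentParams", "IBDSegment", "call_segments", "write_segments_bed"]


@dataclass(frozen=True)
class SegmentParams:
    window_markers: int = 10
    sharing_threshold: float = 0.5  # exclusive: sharing must be > threshold

    def __post_init__(self):
        if self.window_markers < 1:
            raise ValueError("window_markers must be >= 1")
        if not 0.0 <= self.sharing_threshold < 1.0:
            raise ValueError("sharing_threshold must be in [0, 1)")


@dataclass(frozen=True)
class IBDSegment:
    """Interval over which a family's affected members are declared IBD.

    ``start_bp``/``end_bp`` are the 1-based inclusive positions of the first
    and last qualifying markers (outermost-marker convention).
    """

    family_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


def call_segments(
    profile,
    markers: Sequence[MapMarker],
    params: SegmentParams = SegmentParams(),
) -> list[IBDSegment]:
    """Call IBD segments from a :class:`~pedibd.sharing.SharingProfile`.

    ``markers`` supplies physical positions and must match the profile's
    marker ids in order.
    """
    pos = {m.marker_id: m.position_bp for m in markers}
    missing = [m for m in profile.marker_ids if m not in pos]
    if missing:
        raise ValueError(f"profile markers absent from map: {missing[:3]}")
    sharing = np.asarray(profile.sharing, dtype=float)
    n = len(sharing)
    if n == 0:
        return []
    above = sharing > params.sharing_threshold
    w = params.window_markers

    flagged = np.zeros(n, dtype=bool)
    if n < w:
        if above.all():
            flagged[:] = True
    else:
        # runs of consecutive above-threshold markers of length >= w
        i = 0
        while i < n:
            if above[i]:
                j = i
                while j < n and above[j]:
                    j += 1
                if j - i >= w:
                    flagged[i:j] = True
                i = j
            else:
                i += 1

    segments: list[IBDSegment] = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            segments.append(
                IBDSegment(
                    family_id=profile.family_id,
                    chrom=profile.chrom,
                    start_bp=pos[profile.marker_ids[i]],
                    end_bp=pos[profile.marker_ids[j - 1]],
                    n_markers=j - i,
                )
            )
            i = j
        else:
            i += 1
    return segments


def write_segments_bed(path, segments: Sequence[IBDSegment]) -> None:
    """BED export: 0-based half-open (start_bp - 1, end_bp), name = family."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.family_id}\n")
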