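"""Conserved non-coding region calling from a pairwise alignment.

The caller mirrors a VISTA-style screen: percent identity in a sliding window
over reference bases, runs above a homology threshold (70% by default) merged
across short gaps, then filtered by length bounds, annotated-exon exclusion
and a blacklist of previously described elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_core import GenomicInterval

__all__ = [
    "ConservedRegion",
    "window_identity",
    "call_conserved_regions",
    "filter_candidates",
    "regions_to_bed_intervals",
]


@dataclass(frozen=True)
class ConservedRegion:
    """A conserved interval in reference-species coordinates.

    ``identity`` is the mean windowed identity over the region, in [0, 1].
    """

    interval: GenomicInterval
    identity: float

    @property
    def length_bp(self) -> int:
        return len(self.interval)


def window_identity(aln_ref: str, aln_other: str, window_bp: int) -> np.ndarray:
    """Per-reference-base identity profile of a pairwise alignment.

    For each reference (non-gap) base the identity is the match fraction over
    a window of ``window_bp`` reference bases centred there; near the sequence
    ends the window is shifted to stay fully inside, so the profile length
    equals the number of reference bases and edge values remain full-window
    averages. A gap or N on either side counts as a mismatch.
    """
    if len(aln_ref) != len(aln_other):
        raise ValueError(
            f"aligned lengths differ: {len(aln_ref)} vs {len(aln_other)}"
        )
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    ref = np.frombuffer(aln_ref.upper().encode(), dtype="S1")
    oth = np.frombuffer(aln_other.upper().encode(), dtype="S1")
    ref_pos = ref != b"-"
    n_ref = int(ref_pos.sum())
    if window_bp > n_ref:
        raise ValueError(f"window ({window_bp}) larger than reference length ({n_ref})")
    good = (ref == oth) & (ref != b"N") & (ref != b"-")
    match = good[ref_pos].astype(float)

    cs = np.concatenate([[0.0], np.cumsum(match)])
    centers = np.arange(n_ref)
    starts = np.clip(centers - window_bp // 2, 0, n_ref - window_bp)
    return (cs[starts + window_bp] - cs[starts]) / window_bp


def call_conserved_regions(
    profile: np.ndarray,
    min_identity: float,
    window_bp: int,
    chrom: str = "ref",
    offset: int = 0,
) -> list[ConservedRegion]:
    """Maximal runs of the profile at or above ``min_identity``.

    Runs separated by fewer than ``window_bp / 2`` bases are merged (a single
    element should not fragment into sub-threshold slivers); the region
    identity is the profile mean over the merged span. ``offset`` shifts
    profile coordinates into chromosome coordinates.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty identity profile")
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    above = profile >= min_identity
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(profile.size)

    merge_gap = window_bp / 2
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        ConservedRegion(
            interval=GenomicInterval(chrom, offset + s, offset + e),
            identity=float(profile[s:e].mean()),
        )
        for s, e in merged
    ]


def filter_candidates(
    regions: Sequence[ConservedRegion],
    exons: Sequence[GenomicInterval] = (),
    blacklist: Sequence[GenomicInterval] = (),
    min_len: int = 150,
    max_len: int = 2100,
) -> list[ConservedRegion]:
    """Drop regions that touch an exon or blacklisted element (>=1 bp
    overlap) or fall outside the closed length bounds [min_len, max_len].
    Input order is preserved."""
    out = []
    for r in regions:
        if not (min_len <= r.length_bp <= max_len):
            continue
        if any(r.interval.overlaps(e) for e in exons):
            continue
        if any(r.interval.overlaps(b) for b in blacklist):
            continue
        out.append(r)
    return out


def regions_to_bed_intervals(regions: Sequence[ConservedRegion]) -> list[GenomicInterval]:
    """Conserved regions as BED intervals, identity scaled 0-1000 in the
    score column."""
    return [
        GenomicInterval(
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            name=r.interval.name,
            value=round(1000 * r.identity),
        )
        for r in regions
    ]
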