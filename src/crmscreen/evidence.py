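"""Chromatin-mark evidence scoring and signed candidate labelling.

A conserved region becomes a potential cis-regulatory module (PCRM) when it
carries three or more distinct enhancer-associated mark types (H3K27ac,
H3K4me2, p300, RNAP2, Med12 in the default configuration), no repressive
mark (H3K27me3), and at least one predicted transcription-factor binding
site. Retained candidates are numbered by distance rank from the promoter,
negative upstream and positive downstream of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .conservation import ConservedRegion
from .genome_core import GenomicInterval

__all__ = [
    "DEFAULT_ACTIVE_MARKS",
    "DEFAULT_REPRESSIVE_MARKS",
    "EvidenceProfile",
    "PcrmCandidate",
    "count_marks",
    "classify_pcrm",
    "label_pcrms",
]

DEFAULT_ACTIVE_MARKS = frozenset({"H3K27ac", "H3K4me2", "p300", "RNAP2", "Med12"})
DEFAULT_REPRESSIVE_MARKS = frozenset({"H3K27me3"})


@dataclass(frozen=True)
class EvidenceProfile:
    """Mark-type support for one conserved region.

    Marks are counted as dataset types, not peak instances: two peaks of the
    same mark overlapping the region contribute one mark.
    """

    region: ConservedRegion
    marks_present: frozenset[str]
    n_active_marks: int
    repressive_overlap: bool
    has_tfbs: bool


@dataclass(frozen=True)
class PcrmCandidate:
    """An accepted candidate with its signed positional label.

    Negative labels are upstream of the promoter (by gene strand), positive
    downstream; |label| is the distance rank on that side (1 = nearest).
    """

    profile: EvidenceProfile
    label: int
    distance_to_promoter_bp: int

    def __post_init__(self) -> None:
        if self.label == 0:
            raise ValueError("label must be non-zero")


def count_marks(
    region: ConservedRegion,
    peak_tracks: Mapping[str, Sequence[GenomicInterval]],
    active_marks: frozenset[str] = DEFAULT_ACTIVE_MARKS,
    repressive_marks: frozenset[str] = DEFAULT_REPRESSIVE_MARKS,
    has_tfbs: bool = False,
) -> EvidenceProfile:
    """Score a region by which mark tracks have >=1 peak overlapping it by
    >=1 bp."""
    if active_marks & repressive_marks:
        raise ValueError("active and repressive mark sets must be disjoint")
    known = active_marks | repressive_marks
    unknown = set(peak_tracks) - known
    if unknown:
        raise ValueError(f"unknown mark name(s) in tracks: {sorted(unknown)}")
    present = frozenset(
        mark for mark, peaks in peak_tracks.items()
        if any(region.interval.overlaps(p) for p in peaks)
    )
    return EvidenceProfile(
        region=region,
        marks_present=present,
        n_active_marks=len(present & active_marks),
        repressive_overlap=bool(present & repressive_marks),
        has_tfbs=has_tfbs,
    )


def classify_pcrm(profile: EvidenceProfile, min_marks: int = 3) -> bool:
    """Accept iff >= min_marks active mark types, no repressive mark, and at
    least one predicted binding site."""
    return (
        profile.n_active_marks >= min_marks
        and not profile.repressive_overlap
        and profile.has_tfbs
    )


def label_pcrms(
    candidates: Sequence[EvidenceProfile],
    promoter: GenomicInterval,
    gene_strand: str = "+",
) -> list[PcrmCandidate]:
    """Assign signed distance-rank labels relative to the promoter.

    Upstream/downstream is resolved by gene strand (for a '-' gene, larger
    coordinates are upstream). Each side is numbered 1..k by increasing
    midpoint distance, ties broken by start coordinate; upstream labels are
    negated. A candidate overlapping the promoter has no unambiguous side
    and raises.
    """
    if gene_strand not in {"+", "-"}:
        raise ValueError("gene_strand must be '+' or '-'")
    for c in candidates:
        if c.region.interval.chrom != promoter.chrom:
            raise ValueError(
                f"candidate on {c.region.interval.chrom} but promoter on {promoter.chrom}"
            )
        if c.region.interval.overlaps(promoter):
            raise ValueError(
                f"candidate {c.region.interval} overlaps the promoter: side is ambiguous"
            )
    pmid = promoter.midpoint
    upstream, downstream = [], []
    for c in candidates:
        mid = c.region.interval.midpoint
        is_upstream = (mid < pmid) if gene_strand == "+" else (mid > pmid)
        (upstream if is_upstream else downstream).append(c)

    def ranked(side: list[EvidenceProfile]) -> list[tuple[EvidenceProfile, int]]:
        order = sorted(
            side,
            key=lambda c: (abs(c.region.interval.midpoint - pmid), c.region.interval.start),
        )
        return [(c, i + 1) for i, c in enumerate(order)]

    out = [
        PcrmCandidate(
            profile=c,
            label=-rank,
            distance_to_promoter_bp=int(round(abs(c.region.interval.midpoint - pmid))),
        )
        for c, rank in ranked(upstream)
    ] + [
        PcrmCandidate(
            profile=c,
            label=rank,
            distance_to_promoter_bp=int(round(abs(c.region.interval.midpoint - pmid))),
        )
        for c, rank in ranked(downstream)
    ]
    return out
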