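"""Insulation-score TAD calling and 3D/accessibility annotation.

The TAD caller follows the multi-scale insulation-square approach used by
hicFindTADs-style tools: for each bin the mean contact in a square window
crossing the diagonal is computed at several window sizes between a minimum
and maximum depth; boundaries are local minima of the scale-averaged profile
that pass (a) a prominence test ("delta", on the min-max-normalised profile)
and (b) a one-sided rank-sum comparison of intra-domain versus cross-boundary
contacts ("threshold" on the p-value). It is inspired by, not bit-identical
to, the hicFindTADs command. The input matrix is assumed already normalised;
no balancing is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu

from .genome_core import ContactMatrix, GenomicInterval

__all__ = [
    "InsulationProfile",
    "TadSet",
    "insulation_profile",
    "call_tads",
    "boundary_ctcf_concordance",
    "same_tad",
    "is_accessible",
]


@dataclass
class InsulationProfile:
    """Per-bin mean contact in diagonal-crossing squares, one row per scale.

    ``scores[s, i]`` is the mean of the square ``M[i-w : i, i+1 : i+1+w]``
    for window ``w = window_bins[s]``; NaN where the window does not fit.
    """

    cm: ContactMatrix
    window_bins: list[int]
    scores: np.ndarray  # n_scales x n_bins, NaN where undefined

    def averaged(self) -> np.ndarray:
        """Scale-averaged profile; NaN wherever any scale is undefined, so
        boundary candidates are only considered where every window fits."""
        return self.scores.mean(axis=0)


@dataclass
class TadSet:
    """Accepted boundaries (bin indices) and the domains between them.

    A boundary bin belongs to the downstream domain, so domains tile the
    covered region without overlap.
    """

    boundaries: list[int]
    boundary_bins: list[GenomicInterval]
    domains: list[GenomicInterval]
    params: dict

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")


def insulation_profile(
    cm: ContactMatrix,
    min_depth_bp: int = 3000,
    max_depth_bp: int = 31500,
    n_scales: int = 3,
) -> InsulationProfile:
    """Multi-scale insulation profile with window sizes (in bins) evenly
    spaced between min and max depth."""
    bw = cm.bin_width
    if min_depth_bp < bw:
        raise ValueError(f"min_depth_bp ({min_depth_bp}) smaller than bin width ({bw})")
    if max_depth_bp < min_depth_bp:
        raise ValueError("max_depth_bp must be >= min_depth_bp")
    w_min, w_max = min_depth_bp // bw, max_depth_bp // bw
    windows = sorted({int(round(w)) for w in np.linspace(w_min, w_max, max(1, n_scales))})
    n = cm.n_bins
    M = cm.matrix
    scores = np.full((len(windows), n), np.nan)
    for s, w in enumerate(windows):
        for i in range(w, n - w):
            scores[s, i] = M[i - w : i, i + 1 : i + 1 + w].mean()
    return InsulationProfile(cm=cm, window_bins=windows, scores=scores)


def _boundary_samples(M: np.ndarray, i: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Intra-domain (both flanking squares, off-diagonal cells) and
    cross-boundary contact samples around bin i."""
    left = M[i - w : i, i - w : i]
    right = M[i + 1 : i + 1 + w, i + 1 : i + 1 + w]
    iu = np.triu_indices(w, k=1)
    intra = np.concatenate([left[iu], right[iu]])
    cross = M[i - w : i, i + 1 : i + 1 + w].ravel()
    return intra, cross


def call_tads(
    profile: InsulationProfile,
    threshold: float = 0.05,
    delta: float = 0.01,
) -> TadSet:
    """Call TAD boundaries from an insulation profile.

    Candidates are local minima of the scale-averaged profile separated by at
    least the median insulation window. A candidate is accepted iff its
    prominence on the min-max-normalised profile is >= ``delta`` and a
    one-sided Mann-Whitney test finds cross-boundary contacts significantly
    lower than intra-domain contacts at p < ``threshold``.
    """
    avg = profile.averaged()
    defined = ~np.isnan(avg)
    if not defined.any():
        raise ValueError("insulation profile entirely undefined")
    n = avg.size
    lo, hi = float(np.nanmin(avg)), float(np.nanmax(avg))
    if hi > lo:
        norm = (avg - lo) / (hi - lo)
    else:
        norm = np.zeros_like(avg)  # constant profile: no boundaries possible
    # fill undefined edges with the profile max so they cannot become minima
    filled = np.where(defined, norm, 1.0)

    min_sep = int(np.median(profile.window_bins))
    candidates, _ = find_peaks(-filled, prominence=delta, distance=max(1, min_sep))

    M = profile.cm.matrix
    accepted = []
    for i in candidates:
        if not defined[i]:
            continue
        w = min(max(profile.window_bins), i, n - 1 - i)
        if w < 2:
            continue
        intra, cross = _boundary_samples(M, int(i), w)
        if intra.size == 0 or cross.size == 0:
            continue
        p = mannwhitneyu(cross, intra, alternative="less").pvalue
        if p < threshold:
            accepted.append(int(i))

    bins = profile.cm.bins
    chrom = bins[0].chrom
    edges = [0] + accepted + [len(bins)]
    domains = [
        GenomicInterval(chrom, bins[a].start, bins[b - 1].end, name=f"domain_{k}")
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
        if b > a
    ]
    return TadSet(
        boundaries=accepted,
        boundary_bins=[bins[b] for b in accepted],
        domains=domains,
        params={
            "threshold": threshold,
            "delta": delta,
            "window_bins": list(profile.window_bins),
        },
    )


def boundary_ctcf_concordance(
    tads: TadSet,
    ctcf_peaks: Sequence[GenomicInterval],
    tol_bp: int,
) -> float | None:
    """Fraction of boundaries whose bin midpoint lies within tol_bp of a
    CTCF peak midpoint; None (not 0) when there are no boundaries."""
    if not tads.boundaries:
        return None
    if not ctcf_peaks:
        return 0.0
    peak_mids = np.array([p.midpoint for p in ctcf_peaks])
    hits = 0
    for bb in tads.boundary_bins:
        if np.min(np.abs(peak_mids - bb.midpoint)) <= tol_bp:
            hits += 1
    return hits / len(tads.boundaries)


def _domain_index(tads: TadSet, position: float) -> int:
    for k, d in enumerate(tads.domains):
        if d.start <= position < d.end:
            return k
    raise ValueError(f"position {position} outside the covered span")


def same_tad(a: GenomicInterval, b: GenomicInterval, tads: TadSet) -> bool:
    """True iff the midpoints of both intervals fall in the same domain.

    A midpoint on a boundary bin belongs to the downstream domain (domains
    are half-open and start at the boundary bin).
    """
    return _domain_index(tads, a.midpoint) == _domain_index(tads, b.midpoint)


def is_accessible(
    region: GenomicInterval,
    atac_peaks: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> bool:
    """True iff the region overlaps any open-chromatin peak by at least
    min_overlap_bp."""
    return any(region.overlaps(p, min_bp=min_overlap_bp) for p in atac_peaks)
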