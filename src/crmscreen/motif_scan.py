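"""Position-weight-matrix scanning with exact score p-values.

The p-value of a log-odds score is computed exactly by dynamic programming:
per-column scores are rounded to a fixed granularity and the distribution of
the window score under the background model is built by convolving the four-
valued per-column score distributions. The p-value semantics are per-window —
the probability that a single random background window scores at least as
high — matching the usual JASPAR/UCSC track convention. IUPAC core motifs
(e.g. the Ets core GGAA or the Tcf/Lef core SCTTTGATS) are matched by
degenerate-alphabet lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_core import GenomicInterval, SequenceRecord

__all__ = [
    "PWM",
    "MotifHit",
    "CoreMotif",
    "ScoreDistribution",
    "IUPAC",
    "pwm_from_counts",
    "parse_jaspar",
    "score_distribution",
    "exact_pvalue_threshold",
    "scan_sequence",
    "matches_core",
    "find_core",
    "reverse_complement",
    "hits_to_bed_intervals",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Log-odds motif model built from a count matrix and a background.

    Each log-odds cell is
    ``log2(((count + pseudocount*bg) / (colsum + pseudocount)) / bg)``
    with the pseudocount split across letters in proportion to the background.
    """

    name: str
    counts: np.ndarray        # 4 x L, rows A,C,G,T
    background: np.ndarray    # 4 probabilities
    pseudocount: float
    log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"counts must be 4 x L with L >= 1, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        colsum = counts.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError("count matrix has an all-zero column")
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValueError("background must be 4 strictly positive probabilities")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        p = (counts + self.pseudocount * bg[:, None]) / (colsum + self.pseudocount)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "log_odds", np.log2(p / bg[:, None]))

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence; the interval is always in reference
    coordinates, with the strand flag marking reverse-complement matches."""

    pwm_name: str
    interval: GenomicInterval
    score: float   # log-odds, bits (granularity-rounded)
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")


@dataclass(frozen=True)
class CoreMotif:
    """A short degenerate (IUPAC) consensus marking the essential contact
    bases of a binding site family."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad or not self.iupac:
            raise ValueError(f"invalid IUPAC core {self.iupac!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


def pwm_from_counts(
    counts,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
    name: str = "pwm",
) -> PWM:
    """Build a PWM from a 4 x L count matrix (rows A, C, G, T)."""
    if background is None:
        background = np.full(4, 0.25)
    return PWM(name=name, counts=np.asarray(counts, dtype=float),
               background=np.asarray(background, dtype=float), pseudocount=pseudocount)


def parse_jaspar(
    path: str | Path,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> list[PWM]:
    """Read a JASPAR flat PFM file (one or more matrices).

    Accepts both the bracketed form (``A  [ 4 19 0 ]``) and bare 4-row count
    matrices under each ``>`` header.
    """
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, name
        if name is None and not rows:
            return
        if len(rows) != 4:
            raise ValueError(f"{path}: matrix {name!r} has {len(rows)} rows, need 4 (A,C,G,T)")
        pwms.append(pwm_from_counts(np.array(rows), background, pseudocount, name or "pwm"))
        rows = []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else "pwm"
                continue
            body = line
            if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(x) for x in body.split()])
    flush()
    if not pwms:
        raise ValueError(f"{path}: no matrices found")
    return pwms


class ScoreDistribution:
    """Exact distribution of the PWM window score under the background.

    Column scores are rounded to integer multiples of ``granularity`` (bits)
    and convolved position by position, so tail probabilities are exact for
    the rounded score; the rounding error of a reported score is at most
    ``L * granularity / 2``.
    """

    def __init__(self, pwm: PWM, granularity: float = 0.01):
        if granularity <= 0:
            raise ValueError("granularity must be > 0")
        self.pwm = pwm
        self.granularity = float(granularity)
        self.units = np.rint(pwm.log_odds / granularity).astype(np.int64)  # 4 x L

        # position-wise convolution over integer score offsets
        probs = np.array([1.0])
        offset = 0  # score units of probs[0]
        for j in range(pwm.length):
            col = self.units[:, j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(probs.size + (hi - lo), dtype=float)
            for b in range(4):
                shift = int(col[b]) - lo
                new[shift : shift + probs.size] += pwm.background[b] * probs
            probs = new
            offset += lo
        self.offset = offset
        self.probs = probs
        # survival[i] = P(score_units >= offset + i)
        self.survival = probs[::-1].cumsum()[::-1]
        if np.count_nonzero(probs) <= 1:
            raise ValueError(
                "granularity too coarse: all achievable scores collapse to one atom"
            )

    @property
    def min_score(self) -> float:
        return self.offset * self.granularity

    @property
    def max_score(self) -> float:
        return (self.offset + self.probs.size - 1) * self.granularity

    def pvalue_of_units(self, units: int) -> float:
        i = units - self.offset
        if i <= 0:
            return 1.0
        if i >= self.survival.size:
            return 0.0
        return float(self.survival[i])

    def pvalue_of(self, score: float) -> float:
        """P(window score >= score) under the background, on the rounded
        score scale."""
        return self.pvalue_of_units(int(np.rint(score / self.granularity)))

    def threshold(self, alpha: float) -> float:
        """Smallest achievable score s* with P(score >= s*) <= alpha."""
        if not (0 < alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        ok = np.flatnonzero((self.survival <= alpha) & (self.probs > 0))
        if ok.size == 0:
            # even the top atom exceeds alpha; one granule above it has tail 0
            return self.max_score + self.granularity
        return (self.offset + int(ok[0])) * self.granularity


def score_distribution(pwm: PWM, granularity: float = 0.01) -> ScoreDistribution:
    return ScoreDistribution(pwm, granularity)


def exact_pvalue_threshold(pwm: PWM, alpha: float, granularity: float = 0.01) -> float:
    """Score threshold s* such that a random background window scores >= s*
    with probability at most alpha."""
    return score_distribution(pwm, granularity).threshold(alpha)


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    for b, i in _BASE_INDEX.items():
        idx[arr == b.encode()] = i
    return idx


def scan_sequence(
    seq: SequenceRecord | str,
    pwm: PWM,
    alpha: float = 1e-2,
    granularity: float = 0.01,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan both strands for windows with exact p-value < alpha.

    Hit intervals are reference-coordinate windows with a strand flag; a hit
    on '-' means the reverse complement of the window matches. Windows
    containing N are skipped. Hits are sorted by start, '+' before '-'.
    """
    if isinstance(seq, SequenceRecord):
        chrom, s = seq.id, seq.seq
    else:
        chrom, s = "seq", str(seq).upper()
    L = pwm.length
    if len(s) < L:
        return []
    if dist is None:
        dist = score_distribution(pwm, granularity)
    units = dist.units
    units_rc = units[::-1, ::-1]  # complement rows, reverse columns

    idx = _encode(s)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)  # N windows masked out below
    cols = np.arange(L)
    hits: list[MotifHit] = []
    for strand, u in (("+", units), ("-", units_rc)):
        scores = u[safe, cols].sum(axis=1)
        for i in np.flatnonzero(valid):
            p = dist.pvalue_of_units(int(scores[i]))
            if p < alpha:
                hits.append(
                    MotifHit(
                        pwm_name=pwm.name,
                        interval=GenomicInterval(chrom, int(i), int(i) + L, strand=strand),
                        score=float(scores[i]) * dist.granularity,
                        pvalue=p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def matches_core(window: str, core: CoreMotif) -> bool:
    """True iff every base of the window lies in the IUPAC class at that
    position of the core."""
    if len(window) != len(core):
        raise ValueError(f"window length {len(window)} != core length {len(core)}")
    return all(b in IUPAC[c] for b, c in zip(window.upper(), core.iupac))


def find_core(seq: str, core: CoreMotif) -> list[int]:
    """All offsets where the core matches (forward strand)."""
    k = len(core)
    return [i for i in range(len(seq) - k + 1) if matches_core(seq[i : i + k], core)]


def hits_to_bed_intervals(hits: Iterable[MotifHit]) -> list[GenomicInterval]:
    """Hits as BED6 intervals; score column = round(-10*log10(pvalue))."""
    return [
        GenomicInterval(
            h.interval.chrom, h.interval.start, h.interval.end,
            strand=h.interval.strand, name=h.pwm_name,
            value=round(-10 * np.log10(h.pvalue)),
        )
        for h in hits
    ]
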