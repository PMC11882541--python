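"""Substitution-only disruption of core binding sites.

A disruption plan replaces the minimal number of bases needed to write a
restriction-enzyme recognition sequence over the core of a binding site
(GGAA for Ets, SCTTTGATS for Tcf/Lef, TAATTA for homeodomain sites), so the
edit both destroys the site and becomes screenable by digest. Plans are then
re-scanned against the full PWM set to confirm no new predicted sites were
created, mirroring the usual design/recheck loop of site-directed
mutagenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .motif_scan import (
    IUPAC,
    CoreMotif,
    MotifHit,
    PWM,
    ScoreDistribution,
    find_core,
    matches_core,
    scan_sequence,
    score_distribution,
)

__all__ = [
    "RestrictionEnzyme",
    "MutagenesisPlan",
    "design_core_disruption",
    "verify_no_gain",
    "pairwise_site_distance",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition sequence; IUPAC degeneracy allowed."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad or not self.recognition:
            raise ValueError(f"invalid recognition sequence {self.recognition!r}")
        object.__setattr__(self, "recognition", self.recognition.upper())

    def __len__(self) -> int:
        return len(self.recognition)


@dataclass
class MutagenesisPlan:
    """An accepted substitution set and its verification state.

    ``substitutions`` are (absolute offset, ref base, alt base); the mutated
    sequence has the same length as the wildtype. ``gained_hits`` is filled
    by :func:`verify_no_gain` and must be empty for the plan to stand.
    """

    target_hit: MotifHit
    core: CoreMotif
    enzyme: RestrictionEnzyme
    enzyme_offset: int
    substitutions: list[tuple[int, str, str]]
    mutated_sequence: str
    lost_core: bool
    gained_hits: list[MotifHit] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


def _concrete_base(iupac_code: str, current: str) -> str:
    """Base to write for a degenerate enzyme position: keep the current base
    when allowed, else the alphabetically first member of the class."""
    allowed = IUPAC[iupac_code]
    if current in allowed:
        return current
    return min(allowed)


def _core_destroyed(mut: str, core: CoreMotif, core_start: int, core_end: int) -> bool:
    """True iff no core match remains at any offset overlapping the original
    core span."""
    k = len(core)
    lo = max(0, core_start - k + 1)
    hi = min(len(mut) - k, core_end - 1)
    for off in range(lo, hi + 1):
        if matches_core(mut[off : off + k], core):
            return False
    return True


def design_core_disruption(
    seq: str,
    hit: MotifHit,
    core: CoreMotif,
    enzymes: Sequence[RestrictionEnzyme],
    max_subs: int = 4,
    pwm_set: Sequence[PWM] | None = None,
    alpha: float = 1e-2,
) -> MutagenesisPlan | None:
    """Search enzyme placements overlapping the core and pick the cheapest.

    Placements are ranked by substitution count, ties broken by position then
    enzyme order; the chosen edit must leave no core match at any offset
    overlapping the original core. When a ``pwm_set`` is given the redesign
    loop is built in: placements whose edit creates any new predicted site at
    p < ``alpha`` are rejected and the next-cheapest clean placement is taken
    (the plan's ``gained_hits`` is then verified empty). Returns None (failure
    sentinel) when no admissible placement with <= max_subs substitutions
    exists.
    """
    seq = seq.upper()
    if not enzymes:
        raise ValueError("enzyme list must be non-empty")
    if max_subs < 0:
        raise ValueError("max_subs must be >= 0")
    window = seq[hit.interval.start : hit.interval.end]
    offsets = find_core(window, core)
    if not offsets:
        raise ValueError("hit window contains no core match")
    core_start = hit.interval.start + offsets[0]
    core_end = core_start + len(core)

    candidates: list[tuple[tuple[int, int, int], MutagenesisPlan]] = []
    for ei, enz in enumerate(enzymes):
        m = len(enz)
        if m > len(seq):
            raise ValueError(f"enzyme {enz.name} longer than the sequence")
        # placements overlapping [core_start, core_end)
        for pos in range(max(0, core_start - m + 1), min(len(seq) - m, core_end - 1) + 1):
            subs = []
            for j, code in enumerate(enz.recognition):
                cur = seq[pos + j]
                alt = _concrete_base(code, cur)
                if alt != cur:
                    subs.append((pos + j, cur, alt))
            if len(subs) > max_subs:
                continue
            mut = list(seq)
            for off, _ref, alt in subs:
                mut[off] = alt
            mut_s = "".join(mut)
            if not _core_destroyed(mut_s, core, core_start, core_end):
                continue
            plan = MutagenesisPlan(
                target_hit=hit,
                core=core,
                enzyme=enz,
                enzyme_offset=pos,
                substitutions=subs,
                mutated_sequence=mut_s,
                lost_core=True,
            )
            candidates.append(((len(subs), pos, ei), plan))

    for _key, plan in sorted(candidates, key=lambda kp: kp[0]):
        if pwm_set is not None:
            gained, _lost = verify_no_gain(seq, plan.mutated_sequence, pwm_set, alpha)
            if gained:
                continue
        return plan
    return None


def verify_no_gain(
    wt_seq: str,
    mut_seq: str,
    pwm_set: Sequence[PWM],
    alpha: float = 1e-2,
    granularity: float = 0.01,
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Re-scan wildtype and mutant; report (gained, lost) predicted sites.

    A hit is identified by (PWM, interval, strand); gained hits exist in the
    mutant only, lost hits in the wildtype only. Both sequences are scanned
    with the same exact-p-value threshold used for discovery.
    """
    if len(wt_seq) != len(mut_seq):
        raise ValueError("wildtype and mutant sequences differ in length")
    gained: list[MotifHit] = []
    lost: list[MotifHit] = []
    for pwm in pwm_set:
        dist = score_distribution(pwm, granularity)
        wt_hits = scan_sequence(wt_seq, pwm, alpha, dist=dist)
        mut_hits = scan_sequence(mut_seq, pwm, alpha, dist=dist)
        key = lambda h: (h.pwm_name, h.interval.start, h.interval.end, h.interval.strand)
        wt_keys = {key(h) for h in wt_hits}
        mut_keys = {key(h) for h in mut_hits}
        gained.extend(h for h in mut_hits if key(h) not in wt_keys)
        lost.extend(h for h in wt_hits if key(h) not in mut_keys)
    return gained, lost


def pairwise_site_distance(hits: Sequence[MotifHit]) -> list[tuple[MotifHit, MotifHit, int]]:
    """Edge-to-edge distances between all pairs of sites on one sequence;
    overlapping sites have distance 0."""
    if len(hits) < 2:
        raise ValueError("need at least 2 hits")
    out = []
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i].interval, hits[j].interval
            d = max(0, max(a.start, b.start) - min(a.end, b.end))
            out.append((hits[i], hits[j], d))
    return out
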