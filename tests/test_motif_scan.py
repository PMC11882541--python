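import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmscreen import motif_scan as ms
from conftest import random_pwm


def brute_force_tails(pwm: ms.PWM, granularity: float) -> dict[int, float]:
    """Independent oracle: enumerate all 4^L words under the background with
    the same per-column granularity rounding as the DP."""
    units = np.rint(pwm.log_odds / granularity).astype(int)
    mass: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=pwm.length):
        s = int(sum(units[b, j] for j, b in enumerate(word)))
        p = math.prod(pwm.background[b] for b in word)
        mass[s] = mass.get(s, 0.0) + p
    atoms = sorted(mass)
    tails = {}
    acc = 0.0
    for s in reversed(atoms):
        acc += mass[s]
        tails[s] = acc
    return tails


class TestPwmConstruction:
    def test_uniform_column_zero_log_odds(self):
        pwm = ms.pwm_from_counts([[1], [1], [1], [1]], pseudocount=1e-9)
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-7)

    def test_log_odds_formula(self):
        pwm = ms.pwm_from_counts([[4], [0], [0], [0]], pseudocount=1.0)
        # A cell: log2(((4 + 1*0.25) / (4 + 1)) / 0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2((4 + 0.25) / 5 / 0.25))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            ms.pwm_from_counts(np.zeros((4, 0)))

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="zero column"):
            ms.pwm_from_counts([[1, 0], [1, 0], [1, 0], [1, 0]])

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            ms.pwm_from_counts([[1], [1], [1], [1]], background=[0.5, 0.5, 0.0, 0.0])


class TestExactPvalues:
    def test_single_column_unique_best_letter(self):
        pwm = ms.pwm_from_counts([[10], [1], [1], [1]])
        dist = ms.score_distribution(pwm)
        s_star = dist.threshold(0.25)
        assert s_star == pytest.approx(dist.max_score)  # only the A atom
        assert dist.pvalue_of(s_star) == pytest.approx(0.25)

    def test_alpha_one_gives_min_score(self):
        pwm = ms.pwm_from_counts([[10, 1], [1, 5], [1, 1], [1, 1]])
        dist = ms.score_distribution(pwm)
        assert dist.threshold(1.0) == pytest.approx(dist.min_score)
        assert dist.pvalue_of(dist.min_score) == pytest.approx(1.0)

    def test_collapsed_distribution_rejected(self):
        pwm = ms.pwm_from_counts([[10], [1], [1], [1]])
        with pytest.raises(ValueError, match="granularity"):
            ms.score_distribution(pwm, granularity=1e6)

    @pytest.mark.parametrize("length", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("uniform_bg", [True, False])
    def test_dp_matches_brute_force(self, length, uniform_bg):
        rng = np.random.default_rng(100 * length + uniform_bg)
        pwm = random_pwm(rng, length, uniform_bg)
        dist = ms.score_distribution(pwm, 0.01)
        tails = brute_force_tails(pwm, 0.01)
        for s, tail in tails.items():
            assert dist.pvalue_of_units(s) == pytest.approx(tail, abs=1e-12)

    def test_pvalue_nonincreasing_threshold_nondecreasing(self):
        rng = np.random.default_rng(7)
        pwm = random_pwm(rng, 5)
        dist = ms.score_distribution(pwm)
        scores = np.linspace(dist.min_score, dist.max_score, 50)
        ps = [dist.pvalue_of(s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        thresholds = [dist.threshold(a) for a in (0.5, 0.1, 0.01, 0.001)]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))


class TestScanning:
    def test_consensus_hit_coordinates(self, ets_pwm):
        seq = "TTTT" + ets_pwm.consensus + "TTTT"
        hits = ms.scan_sequence(seq, ets_pwm, alpha=1e-2)
        plus = [h for h in hits if h.interval.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].interval.start, plus[0].interval.end) == (4, 4 + ets_pwm.length)
        assert plus[0].pvalue < 1e-2

    def test_all_n_sequence_empty(self, ets_pwm):
        assert ms.scan_sequence("N" * 50, ets_pwm) == []

    def test_short_sequence_empty(self, ets_pwm):
        assert ms.scan_sequence("ACG", ets_pwm) == []

    def test_minus_hit_reports_reference_window(self, ets_pwm):
        rc = ms.reverse_complement(ets_pwm.consensus)
        seq = "TTTT" + rc + "TTTT"
        hits = ms.scan_sequence(seq, ets_pwm, alpha=1e-2)
        minus = [h for h in hits if h.interval.strand == "-"]
        assert len(minus) == 1
        # interval is the matched reference window, not the reverse complement
        assert (minus[0].interval.start, minus[0].interval.end) == (4, 4 + ets_pwm.length)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_reverse_complement_mirror(self, seed, ets_pwm):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 80))
        n = len(seq)
        fwd = ms.scan_sequence(seq, ets_pwm, alpha=0.05)
        rev = ms.scan_sequence(ms.reverse_complement(seq), ets_pwm, alpha=0.05)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (n - h.interval.end, n - h.interval.start, flip[h.interval.strand],
             round(h.score, 6))
            for h in rev
        )
        direct = sorted(
            (h.interval.start, h.interval.end, h.interval.strand, round(h.score, 6))
            for h in fwd
        )
        assert direct == mirrored

    def test_hits_sorted_plus_before_minus(self, ets_pwm):
        pal = ets_pwm.consensus + ms.reverse_complement(ets_pwm.consensus)
        hits = ms.scan_sequence(pal * 2, ets_pwm, alpha=0.05)
        keys = [(h.interval.start, h.interval.strand) for h in hits]
        assert keys == sorted(keys)


class TestCoreMotifs:
    @pytest.mark.parametrize(
        "window,core,expected",
        [
            ("GGAA", "GGAA", True),
            ("CCTTTGATC", "SCTTTGATS", True),
            ("ACTTTGATC", "SCTTTGATS", False),
            ("TAATTA", "TAATTA", True),
        ],
    )
    def test_matches_core(self, window, core, expected):
        assert ms.matches_core(window, ms.CoreMotif("c", core)) is expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ms.matches_core("GGA", ms.CoreMotif("c", "GGAA"))

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            ms.CoreMotif("c", "GGXA")

    def test_find_core_offsets(self):
        assert ms.find_core("AGGAATGGAA", ms.CoreMotif("ets", "GGAA")) == [1, 6]


class TestJasparIO:
    def test_bracketed_and_bare_rows(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(
            ">M1 m1\nA [ 4 0 ]\nC [ 0 4 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
            ">M2 m2\n1 1\n1 1\n1 1\n1 1\n"
        )
        pwms = ms.parse_jaspar(p)
        assert [p_.name for p_ in pwms] == ["M1", "M2"]
        assert pwms[0].consensus == "AC"

    def test_bed_score_is_phred_scaled_pvalue(self, ets_pwm):
        seq = "TT" + ets_pwm.consensus
        (iv,) = ms.hits_to_bed_intervals(ms.scan_sequence(seq, ets_pwm, 1e-2)[:1])
        hit = ms.scan_sequence(seq, ets_pwm, 1e-2)[0]
        assert iv.value == round(-10 * np.log10(hit.pvalue))
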