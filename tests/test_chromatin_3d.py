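import numpy as np
import pytest

from crmscreen.chromatin_3d import (
    boundary_ctcf_concordance,
    call_tads,
    insulation_profile,
    is_accessible,
    same_tad,
)
from crmscreen.genome_core import ContactMatrix, GenomicInterval
from crmscreen.synthetic_data import synth_contact_matrix


def make_cm(matrix, bin_bp=1000):
    n = matrix.shape[0]
    bins = [GenomicInterval("c", i * bin_bp, (i + 1) * bin_bp) for i in range(n)]
    return ContactMatrix(bins=bins, matrix=matrix)


class TestInsulationProfile:
    def test_constant_matrix_constant_profile(self):
        cm = make_cm(np.full((20, 20), 3.0))
        prof = insulation_profile(cm, min_depth_bp=2000, max_depth_bp=5000, n_scales=2)
        avg = prof.averaged()
        defined = ~np.isnan(avg)
        assert defined.any()
        np.testing.assert_allclose(avg[defined], 3.0)

    def test_zero_inter_block_score_at_junction(self):
        m = np.zeros((20, 20))
        m[:10, :10] = 1.0
        m[10:, 10:] = 1.0
        cm = make_cm(m)
        prof = insulation_profile(cm, min_depth_bp=3000, max_depth_bp=3000, n_scales=1)
        # square at bin 10 with w=3 lies entirely across the block junction
        assert prof.scores[0, 10] == 0.0

    def test_hand_computed_two_by_two_window(self):
        m = np.zeros((6, 6))
        vals = {(1, 3): 2.0, (1, 4): 4.0, (2, 3): 6.0, (2, 4): 8.0}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        cm = make_cm(m)
        prof = insulation_profile(cm, min_depth_bp=2000, max_depth_bp=2000, n_scales=1)
        # w=2 square at i=3: rows {1,2} x cols {4,5}: M[1,4]=4, M[1,5]=0, M[2,4]=8, M[2,5]=0
        assert prof.scores[0, 3] == pytest.approx((4.0 + 0.0 + 8.0 + 0.0) / 4)

    def test_min_depth_below_bin_width_rejected(self):
        cm = make_cm(np.ones((10, 10)))
        with pytest.raises(ValueError, match="bin width"):
            insulation_profile(cm, min_depth_bp=500)

    def test_undefined_at_edges(self):
        cm = make_cm(np.ones((10, 10)))
        prof = insulation_profile(cm, min_depth_bp=3000, max_depth_bp=3000, n_scales=1)
        assert np.isnan(prof.scores[0, 0]) and np.isnan(prof.scores[0, -1])
        assert not np.isnan(prof.scores[0, 5])


class TestCallTads:
    def test_two_planted_blocks_one_boundary(self):
        cm, _ = synth_contact_matrix(
            n_bins=40, bin_bp=3000, boundaries=[20], noise_cv=0.1, seed=5
        )
        prof = insulation_profile(cm, min_depth_bp=9000, max_depth_bp=24000, n_scales=3)
        tads = call_tads(prof)
        assert len(tads.boundaries) == 1
        assert abs(tads.boundaries[0] - 20) <= 1
        assert len(tads.domains) == 2

    def test_constant_matrix_no_boundaries(self):
        cm = make_cm(np.full((40, 40), 2.0))
        prof = insulation_profile(cm, min_depth_bp=3000, max_depth_bp=9000)
        tads = call_tads(prof)
        assert tads.boundaries == []
        assert len(tads.domains) == 1  # single domain tiles the span

    def test_saturating_delta_removes_all_boundaries(self):
        cm, _ = synth_contact_matrix(n_bins=40, bin_bp=3000, boundaries=[20], seed=1)
        prof = insulation_profile(cm, min_depth_bp=9000, max_depth_bp=24000)
        assert call_tads(prof, delta=1.1).boundaries == []

    def test_boundary_count_monotone_in_delta(self):
        cm, _ = synth_contact_matrix(seed=3)
        prof = insulation_profile(cm)
        counts = [len(call_tads(prof, delta=d).boundaries) for d in (0.01, 0.3, 0.95, 1.1)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_boundaries_recovered_across_seeds(self):
        for seed in range(10):
            cm, truth = synth_contact_matrix(seed=seed)
            tads = call_tads(insulation_profile(cm))
            planted = truth["boundaries"]
            assert all(
                any(abs(b - p) <= 1 for b in tads.boundaries) for p in planted
            ), seed
            assert all(
                any(abs(b - p) <= 1 for p in planted) for b in tads.boundaries
            ), seed

    def test_domains_tile_without_overlap(self):
        cm, _ = synth_contact_matrix(seed=2)
        tads = call_tads(insulation_profile(cm))
        for a, b in zip(tads.domains, tads.domains[1:]):
            assert a.end == b.start
        assert tads.domains[0].start == 0


@pytest.fixture(scope="module")
def tads():
    cm, _ = synth_contact_matrix(noise_cv=0.0, seed=0)
    return call_tads(insulation_profile(cm)), cm


class TestAnnotations:

    def test_concordance_values(self, tads):
        ts, cm = tads
        mids = [bb.midpoint for bb in ts.boundary_bins]
        on_peaks = [GenomicInterval("chr_syn", int(m) - 50, int(m) + 50) for m in mids]
        assert boundary_ctcf_concordance(ts, on_peaks, tol_bp=200) == 1.0
        assert boundary_ctcf_concordance(ts, [], tol_bp=200) == 0.0
        half = on_peaks[:1]
        assert boundary_ctcf_concordance(ts, half, tol_bp=200) == pytest.approx(0.5)

    def test_no_boundaries_returns_sentinel(self):
        cm = make_cm(np.full((40, 40), 1.0))
        ts = call_tads(insulation_profile(cm, 3000, 9000))
        assert boundary_ctcf_concordance(ts, [GenomicInterval("c", 0, 10)], 100) is None

    def test_same_tad_symmetric_reflexive(self, tads):
        ts, cm = tads
        d0, d1 = ts.domains[0], ts.domains[1]
        a = GenomicInterval("chr_syn", d0.start + 100, d0.start + 300)
        b = GenomicInterval("chr_syn", d0.end - 300, d0.end - 100)
        c = GenomicInterval("chr_syn", d1.start + 100, d1.start + 300)
        assert same_tad(a, a, ts) and same_tad(a, b, ts) == same_tad(b, a, ts)
        assert same_tad(a, b, ts) is True
        assert same_tad(a, c, ts) is False

    def test_boundary_midpoint_goes_downstream(self, tads):
        ts, cm = tads
        bstart = ts.domains[1].start
        iv = GenomicInterval("chr_syn", bstart, bstart + 2)
        inside_second = GenomicInterval(
            "chr_syn", ts.domains[1].start + 100, ts.domains[1].start + 300
        )
        assert same_tad(iv, inside_second, ts) is True

    def test_out_of_span_rejected(self, tads):
        ts, cm = tads
        far = GenomicInterval("chr_syn", 10**8, 10**8 + 100)
        with pytest.raises(ValueError, match="span"):
            same_tad(far, far, ts)

    def test_is_accessible_overlap_rules(self):
        region = GenomicInterval("c", 100, 200)
        assert is_accessible(region, [GenomicInterval("c", 0, 500)])
        assert not is_accessible(region, [GenomicInterval("c", 200, 300)])
        assert is_accessible(region, [GenomicInterval("c", 199, 300)])  # 1 bp
        assert not is_accessible(
            region, [GenomicInterval("c", 199, 300)], min_overlap_bp=2
        )
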