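"""Change-point detection, signal-area assembly and the pseudomedian."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipsad import (
    ChangePoint,
    SegmentationParams,
    build_cpr_pair,
    chipsad,
    detect_change_points,
    pseudomedian,
    sam_t,
    segment_nontiling,
    segment_tiling,
    t_profile,
)
from chipsad.segmentation import CPR

from conftest import make_track


def walsh_median(values):
    """Brute-force Hodges-Lehmann oracle: explicit double loop."""
    pairs = [
        (values[i] + values[j]) / 2.0
        for i in range(len(values))
        for j in range(i, len(values))
    ]
    return statistics.median(pairs)


def pooled_t_oracle(left_vals, right_vals, s0):
    """Independent recomputation of the SAM relative difference."""
    nl, nr = len(left_vals), len(right_vals)
    ml, mr = statistics.fmean(left_vals), statistics.fmean(right_vals)
    ssl = sum((v - ml) ** 2 for v in left_vals)
    ssr = sum((v - mr) ** 2 for v in right_vals)
    s = math.sqrt((1 / nl + 1 / nr) * (ssl + ssr) / (nl + nr - 2))
    return (mr - ml) / (s + s0)


def _cpr(values, side="left"):
    vals = np.asarray(values, float)
    mean = float(vals.mean())
    return CPR(side, 0, 0, len(vals), len(vals), mean,
               float(((vals - mean) ** 2).sum()), 10 * len(vals))


class TestPseudomedian:
    @pytest.mark.parametrize(
        "values,expected",
        [([4.2], 4.2), ([1, 2, 3], 2.0), ([0, 0, 10], 2.5)],
    )
    def test_known_values(self, values, expected):
        assert pseudomedian(values) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pseudomedian([])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_matches_brute_force_oracle(self, values):
        assert pseudomedian(values) == pytest.approx(
            walsh_median(values), abs=1e-9
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30),
        st.floats(-50, 50, allow_nan=False),
    )
    def test_translation_equivariance(self, values, c):
        shifted = [v + c for v in values]
        assert pseudomedian(shifted) == pytest.approx(
            pseudomedian(values) + c, abs=1e-9
        )


class TestSamT:
    def test_identical_sides_zero(self):
        assert sam_t(_cpr([1.0, 1.0, 1.0]), _cpr([1.0, 1.0, 1.0]), 0.5) == 0.0

    def test_zero_scatter_hand_value(self):
        # s = 0, so t = (2 - 0) / s0 = 4
        assert sam_t(_cpr([0, 0, 0]), _cpr([2, 2, 2]), 0.5) == pytest.approx(4.0)

    def test_matches_pooled_oracle(self):
        left, right, s0 = [0.0, 2.0], [1.0, 3.0], 0.1
        assert sam_t(_cpr(left), _cpr(right), s0) == pytest.approx(
            pooled_t_oracle(left, right, s0)
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=20),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=20),
    )
    def test_antisymmetric(self, lv, rv):
        t1 = sam_t(_cpr(lv), _cpr(rv), 0.2)
        t2 = sam_t(_cpr(rv), _cpr(lv), 0.2)
        assert t1 == pytest.approx(-t2, abs=1e-9)

    def test_degenerate_side_rejected(self):
        with pytest.raises(ValueError):
            sam_t(_cpr([1.0]), _cpr([1.0, 2.0]), 0.1)


class TestBuildCprPair:
    def test_constant_signal_expands_to_cap(self):
        track = make_track([1.0] * 60, step=10)
        params = SegmentationParams(w=10, m_w=2, s0=0.1, max_window_expansion=100)
        left, right = build_cpr_pair(track, 30, params)
        assert left.span <= 100 and right.span <= 100
        assert left.n >= 8 and right.n >= 8  # grew well past the initial window
        assert left.mean_M == 1.0 and left.sd_M == 0.0

    def test_step_halts_expansion(self):
        track = make_track([0.0] * 20 + [2.0] * 20, step=10)
        params = SegmentationParams(w=10, m_w=2, s0=0.1, max_window_expansion=400)
        left, right = build_cpr_pair(track, 20, params)
        assert left.mean_M == 0.0 and right.mean_M == 2.0
        assert left.sd_M == 0.0 and right.sd_M == 0.0

    def test_large_gap_leaves_left_degenerate(self):
        # a 3w hole immediately left of the anchor severs the left window
        from chipsad import ProbeMeasurement, ProbeTrack

        starts = [1, 11, 21, 101, 111, 121, 131]
        probes = [
            ProbeMeasurement(f"p{i}", "chr", "+", s, s + 9, M=0.0)
            for i, s in enumerate(starts)
        ]
        track = ProbeTrack("e", "chr", "+", probes)
        params = SegmentationParams(w=20, m_w=2, s0=0.1)
        left, right = build_cpr_pair(track, 3, params)
        assert left.degenerate
        assert not right.degenerate


class TestProfileAndChangePoints:
    def test_constant_track_all_zero(self):
        track = make_track([1.5] * 40, step=10)
        prof = t_profile(track, SegmentationParams(s0=0.1))
        assert prof and all(t == 0.0 for _, t in prof)

    def test_step_peaks_at_step_anchor(self):
        track = make_track([0.0] * 30 + [2.0] * 30, step=10)
        prof = t_profile(track, SegmentationParams())
        x_max = max(prof, key=lambda p: abs(p[1]))[0]
        assert x_max == track.probes[30].start

    def test_tiny_track_empty_profile(self):
        assert t_profile(make_track([0.0, 1.0, 0.0]), SegmentationParams(m_w=2)) == []

    def test_all_zero_profile_no_change_points(self):
        prof = [(x, 0.0) for x in range(0, 100, 10)]
        assert detect_change_points(prof, 3.0) == []

    def test_single_step_single_change_point(self):
        track = make_track([0.0] * 30 + [2.0] * 30, step=10)
        prof = t_profile(track, SegmentationParams())
        cps = detect_change_points(prof, 3.0)
        assert len(cps) == 1
        assert cps[0].x == track.probes[30].start

    def test_two_separated_steps(self):
        track = make_track([0.0] * 30 + [2.0] * 30 + [0.0] * 30, step=10)
        prof = t_profile(track, SegmentationParams())
        cps = detect_change_points(prof, 3.0)
        assert [cp.x for cp in cps] == [track.probes[30].start, track.probes[60].start]

    def test_opposite_sign_run_splits(self):
        # rise and fall with no eligible anchor between them are two cuts
        prof = [(10, 5.0), (20, -5.0)]
        assert len(detect_change_points(prof, 3.0)) == 2


class TestSegmentAssembly:
    def test_no_change_points_single_area(self):
        track = make_track([1.0] * 20, step=10)
        sas = segment_tiling(track, [])
        assert len(sas) == 1
        assert sas[0].start == 1 and sas[0].n_probes == 20

    def test_one_change_point_partitions(self):
        track = make_track([0.0] * 10 + [2.0] * 10, step=10)
        sas = segment_tiling(track, [ChangePoint(track.probes[10].start, 9.9)])
        assert len(sas) == 2
        assert sas[0].n_probes == 10 and sas[1].n_probes == 10
        assert sas[0].end + 1 == sas[1].start

    def test_nontiling_identical_regions_join(self):
        track = make_track([2.0] * 12, step=10)
        cp = ChangePoint(track.probes[6].start, 9.9)
        sas = segment_nontiling(track, [cp])
        assert len(sas) == 1 and sas[0].pseudomedian_M == 2.0

    def test_nontiling_opposite_small_levels_split(self):
        # PM +0.1 vs -0.1, union PM ~ 0: |0| > 0.2 is false
        track = make_track([0.1] * 8 + [-0.1] * 8, step=10)
        cp = ChangePoint(track.probes[8].start, 9.9)
        sas = segment_nontiling(track, [cp])
        assert len(sas) == 2

    def test_nontiling_three_equal_regions_single_area(self):
        track = make_track([1.5] * 18, step=10)
        cps = [ChangePoint(track.probes[6].start, 9.9),
               ChangePoint(track.probes[12].start, 9.9)]
        sas = segment_nontiling(track, cps)
        assert len(sas) == 1


class TestChipsadEndToEnd:
    def test_noiseless_fixture_boundaries(self, three_transcript_fixture):
        track, transcripts, cfg = three_transcript_fixture
        sas = chipsad(track, SegmentationParams())
        assert len(sas) == 7
        recovered = {(s.start, s.end) for s in sas}
        for t in transcripts:
            assert any(
                abs(s - t.start) <= cfg.step and abs(e - t.end) <= cfg.step
                for s, e in recovered
            )

    def test_disjoint_cover(self, three_transcript_fixture):
        track, _, _ = three_transcript_fixture
        sas = chipsad(track, SegmentationParams())
        covered = sorted((s.probe_lo, s.probe_hi) for s in sas)
        flat = [i for lo, hi in covered for i in range(lo, hi)]
        assert flat == list(range(len(track)))  # every probe exactly once

    def test_empty_track(self):
        from chipsad import ProbeTrack

        assert chipsad(ProbeTrack("e", "chr", "+", []), SegmentationParams()) == []

    def test_path_consistency_uniform_layout(self):
        # well-separated levels on a uniform grid: both paths agree
        track = make_track([0.0] * 25 + [2.0] * 25 + [0.0] * 25, step=10)
        tiling = chipsad(track, SegmentationParams(layout_mode="tiling"))
        nontiling = chipsad(track, SegmentationParams(layout_mode="nontiling"))
        assert [(s.start, s.end) for s in tiling] == [
            (s.start, s.end) for s in nontiling
        ]
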