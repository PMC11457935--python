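import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embgan.evaluation import (
    ErrorTally,
    count_detection_errors,
    count_tracking_errors,
    match_detections,
    performance_by_depth,
    performance_by_time,
    tallies_by_timepoint,
)
from embgan.trackgraph import Detection, TrackGraph


def _det(i, t, center):
    return Detection(id=i, timepoint=t, center=np.asarray(center, float))


def two_track_graph(swap=False):
    """Cells A (y=10) and B (y=20) over two frames; optionally swap links."""
    g = TrackGraph()
    for t in range(2):
        g.add_detection(_det(0, t, (1, 10, 10)))
        g.add_detection(_det(1, t, (1, 20, 10)))
    if swap:
        g.add_edge((0, 0), (1, 1))
        g.add_edge((0, 1), (1, 0))
    else:
        g.add_edge((0, 0), (1, 0))
        g.add_edge((0, 1), (1, 1))
    return g


class TestMatchDetections:
    def test_identical_lists_fully_matched(self):
        dets = [_det(i, 0, (0, i * 5, 0)) for i in range(4)]
        matches = match_detections(dets, dets, radius=1.0)
        assert sorted(matches) == [(i, i) for i in range(4)]

    def test_empty_prediction_all_fn(self):
        truth = [_det(i, 0, (0, i * 5, 0)) for i in range(3)]
        assert match_detections([], truth, radius=1.0) == []

    def test_crossed_pair_matches_brute_force_minimum(self):
        pred = [_det(0, 0, (0, 0, 0)), _det(1, 0, (0, 4, 0))]
        truth = [_det(0, 0, (0, 1, 0)), _det(1, 0, (0, 3, 0))]
        matches = match_detections(pred, truth, radius=10.0)
        # brute force over both permutations
        def cost(perm):
            return sum(
                np.linalg.norm(pred[i].center - truth[j].center)
                for i, j in zip(range(2), perm)
            )
        best = min([(0, 1), (1, 0)], key=cost)
        assert sorted(matches) == sorted(zip(range(2), best))

    def test_cutoff_radius_respected(self):
        pred = [_det(0, 0, (0, 0, 0))]
        truth = [_det(0, 0, (0, 5, 0))]
        assert match_detections(pred, truth, radius=1.0) == []
        assert len(match_detections(pred, truth, radius=6.0)) == 1


class TestDetectionErrors:
    def test_identical_graphs_perfect_rates(self):
        g = two_track_graph()
        tally = count_detection_errors(g, g, radius=1.0)
        assert (tally.det_precision, tally.det_recall, tally.det_accuracy) == (1, 1, 1)

    def test_one_spurious_detection_is_one_fp(self):
        truth = two_track_graph()
        pred = two_track_graph()
        pred.add_detection(_det(9, 0, (1, 40, 40)))
        tally = count_detection_errors(pred, truth, radius=1.0)
        assert (tally.det_fp, tally.det_fn) == (1, 0)

    def test_randomized_fixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        truth_pts = rng.random((6, 3)) * 30
        pred_pts = np.vstack([truth_pts[:4] + rng.normal(0, 0.2, (4, 3)), rng.random((3, 3)) * 30 + 40])
        truth = TrackGraph()
        pred = TrackGraph()
        for i, p in enumerate(truth_pts):
            truth.add_detection(_det(i, 0, p))
        for i, p in enumerate(pred_pts):
            pred.add_detection(_det(i, 0, p))
        tally = count_detection_errors(pred, truth, radius=1.5)
        # exhaustive: best one-to-one assignment over all injections
        best_tp = 0
        for perm in itertools.permutations(range(6), 4):
            tp = sum(
                np.linalg.norm(pred_pts[i] - truth_pts[j]) <= 1.5
                for i, j in enumerate(perm)
            )
            best_tp = max(best_tp, tp)
        assert tally.det_tp == best_tp
        assert tally.det_fp == 7 - best_tp
        assert tally.det_fn == 6 - best_tp

    def test_conservation_identities(self):
        rng = np.random.default_rng(2)
        truth = TrackGraph()
        pred = TrackGraph()
        for i in range(5):
            truth.add_detection(_det(i, 0, rng.random(3) * 20))
        for i in range(7):
            pred.add_detection(_det(i, 0, rng.random(3) * 20))
        tally = count_detection_errors(pred, truth, radius=2.0)
        assert tally.det_tp + tally.det_fn == 5
        assert tally.det_tp + tally.det_fp == 7


class TestTrackingErrors:
    def test_identical_graphs_zero_errors(self):
        g = two_track_graph()
        tally = count_tracking_errors(g, g, radius=1.0)
        assert tally.trk_fp == 0 and tally.trk_fn == 0
        assert tally.trk_tp == 2

    def test_identity_swap_counts_four_errors(self):
        """A two-cell identity swap across one transition costs exactly
        2 FNs (missing correct edges) + 2 FPs (crossing edges)."""
        truth = two_track_graph(swap=False)
        pred = two_track_graph(swap=True)
        tally = count_tracking_errors(pred, truth, radius=1.0)
        assert tally.trk_fn == 2
        assert tally.trk_fp == 2
        assert tally.trk_total_errors == 4
        assert tally.trk_fn_missed_link == 2
        assert tally.trk_fn_missing_detection == 0

    def test_deleted_detection_two_missing_detection_fns(self):
        truth = TrackGraph()
        for t in range(3):
            truth.add_detection(_det(0, t, (1, 10, 10)))
        truth.add_edge((0, 0), (1, 0))
        truth.add_edge((1, 0), (2, 0))
        pred = TrackGraph()
        pred.add_detection(_det(0, 0, (1, 10, 10)))
        pred.add_detection(_det(0, 2, (1, 10, 10)))
        pred.frames.setdefault(1, [])
        tally = count_tracking_errors(pred, truth, radius=1.0)
        assert tally.trk_fn_missing_detection == 2
        assert tally.trk_fn_missed_link == 0
        assert tally.trk_fp == 0

    def test_swap_symmetry_exchanges_fp_and_fn(self):
        a = two_track_graph(swap=False)
        b = two_track_graph(swap=True)
        ab = count_tracking_errors(a, b, radius=1.0)
        ba = count_tracking_errors(b, a, radius=1.0)
        assert (ab.trk_fp, ab.trk_fn) == (ba.trk_fn, ba.trk_fp)
        assert (ab.det_fp, ab.det_fn) == (ba.det_fn, ba.det_fp)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 4))
    @settings(max_examples=15, deadline=None)
    def test_every_inserted_swap_costs_four_errors(self, seed, n_swaps):
        """Randomized fixtures: k disjoint swaps yield exactly 4k errors."""
        rng = np.random.default_rng(seed)
        n_tracks = 2 * n_swaps + rng.integers(0, 3)
        pts = rng.random((n_tracks, 3)) * 100
        truth = TrackGraph()
        pred = TrackGraph()
        for t in range(2):
            for i in range(n_tracks):
                truth.add_detection(_det(i, t, pts[i]))
                pred.add_detection(_det(i, t, pts[i]))
        swapped = rng.permutation(n_tracks)[: 2 * n_swaps]
        partner = {}
        for k in range(n_swaps):
            a, b = swapped[2 * k], swapped[2 * k + 1]
            partner[a], partner[b] = b, a
        for i in range(n_tracks):
            truth.add_edge((0, i), (1, i))
            pred.add_edge((0, i), (1, partner.get(i, i)))
        tally = count_tracking_errors(pred, truth, radius=1.0)
        assert tally.trk_fp == 2 * n_swaps
        assert tally.trk_fn == 2 * n_swaps
        assert tally.trk_total_errors == 4 * n_swaps


class TestPerformanceSeries:
    def _tallies(self, accs):
        out = {}
        for t, a in enumerate(accs):
            tally = ErrorTally()
            tally.trk_tp = int(a * 100)
            tally.trk_fp = 100 - int(a * 100)
            out[t] = tally
        return out

    def test_constant_rates_stay_constant(self):
        series = performance_by_time(self._tallies([0.8] * 30), window=10)
        assert np.allclose(series.precision, 0.8)

    def test_window_one_is_identity(self):
        accs = [0.5, 0.7, 0.9, 0.6]
        series = performance_by_time(self._tallies(accs), window=1)
        assert np.allclose(series.precision, accs)

    def test_matches_brute_force_sliding_mean(self):
        rng = np.random.default_rng(4)
        accs = rng.random(200)
        series = performance_by_time(self._tallies(accs), window=10)
        vals = np.array([t.trk_precision for t in self._tallies(accs).values()])
        for i in (0, 3, 57, 120, 199):
            lo, hi = max(0, i - 4), min(200, i + 6)
            assert series.precision[i] == pytest.approx(vals[lo:hi].mean(), abs=5e-3)

    def test_window_larger_than_series_gives_global_mean(self):
        accs = [0.2, 0.4, 0.6]
        series = performance_by_time(self._tallies(accs), window=100)
        vals = [t.trk_precision for t in self._tallies(accs).values()]
        assert np.allclose(series.precision, np.mean(vals))

    def test_undefined_frames_propagate_as_missing(self):
        tallies = self._tallies([0.5, 0.5])
        tallies[5] = ErrorTally()  # 0/0 frame
        series = performance_by_time(tallies, window=1)
        assert np.isnan(series.precision[-1])

    def test_depth_series_from_tallies(self):
        g = two_track_graph()
        tallies = tallies_by_timepoint(g, g, radius=1.0)
        series = performance_by_time(tallies, window=1, which="detection")
        assert np.allclose(series.accuracy, 1.0)

    def test_depth_binning_localizes_errors(self):
        from embgan.evaluation import tallies_by_depth

        truth = TrackGraph()
        pred = TrackGraph()
        truth.add_detection(_det(0, 0, (2.0, 10, 10)))   # matched, z bin 2
        pred.add_detection(_det(0, 0, (2.0, 10, 10)))
        pred.add_detection(_det(1, 0, (7.0, 40, 40)))    # FP in z bin 7
        tallies = tallies_by_depth(pred, truth, radius=1.0, n_slices=10)
        assert tallies[2].det_tp == 1
        assert tallies[7].det_fp == 1
        series = performance_by_depth(tallies)
        assert series.precision[2] == 1.0 and series.precision[7] == 0.0
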