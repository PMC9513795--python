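"""Adapted-mAP machinery: midpoint distances, greedy matching, AP, coverage."""

import itertools

import numpy as np
import pytest

from pulsedet import metrics
from pulsedet.model import Detection
from pulsedet.simulate import Segment


def det(start, end, score=1.0):
    return Detection(Segment(start, end), score)


class TestMidpointDistance:
    def test_identical(self):
        assert metrics.midpoint_distance_pct(Segment(3.0, 7.0), Segment(3.0, 7.0)) == 0.0

    def test_forced_arithmetic(self):
        """Truth [10,20], prediction [40,50]: |45-15|/10 = 300%."""
        d = metrics.midpoint_distance_pct(Segment(40.0, 50.0), Segment(10.0, 20.0))
        assert d == pytest.approx(300.0)

    def test_hundred_percent_means_one_duration(self):
        """Offset by exactly the truth duration -> 100%."""
        d = metrics.midpoint_distance_pct(Segment(15.0, 25.0), Segment(5.0, 15.0))
        assert d == pytest.approx(100.0)

    def test_zero_length_truth_rejected(self):
        with pytest.raises(ValueError):
            metrics.midpoint_distance_pct(Segment(0.0, 1.0), (5.0, 5.0))


class TestMatchAtThreshold:
    def test_perfect_predictions_all_tp(self):
        truths = [Segment(10.0, 15.0), Segment(40.0, 45.0)]
        preds = [det(10.0, 15.0, 0.9), det(40.0, 45.0, 0.8)]
        res = metrics.match_at_threshold(preds, truths, 10.0)
        assert res.n_tp == 2 and res.n_truths == 2

    def test_one_truth_two_predictions_is_one_to_one(self):
        """The higher-score duplicate wins; the other is a false positive."""
        truths = [Segment(10.0, 20.0)]
        preds = [det(10.5, 20.5, 0.6), det(10.0, 20.0, 0.9)]
        res = metrics.match_at_threshold(preds, truths, 100.0)
        assert res.n_tp == 1
        assert res.tp[0] and not res.tp[1]  # score order: 0.9 first
        assert res.scores[0] == 0.9

    def test_threshold_is_strict(self):
        """Distance exactly equal to the threshold is not a true positive."""
        preds = [det(15.0, 25.0)]  # distance exactly 100% of truth duration
        truths = [Segment(5.0, 15.0)]
        assert metrics.match_at_threshold(preds, truths, 100.0).n_tp == 0
        assert metrics.match_at_threshold(preds, truths, 100.0 + 1e-6).n_tp == 1


class TestAveragePrecision:
    def test_single_exact_prediction(self):
        assert metrics.average_precision([det(1.0, 2.0)], [Segment(1.0, 2.0)],
                                         100.0) == pytest.approx(1.0)

    def test_tp_before_fp_keeps_ap_one(self):
        """With recall saturated by the top-ranked TP, a later FP costs nothing."""
        preds = [det(1.0, 2.0, 0.9), det(50.0, 51.0, 0.5)]
        truths = [Segment(1.0, 2.0)]
        assert metrics.average_precision(preds, truths, 100.0) == pytest.approx(1.0)

    def test_fp_before_tp_halves_ap(self):
        preds = [det(50.0, 51.0, 0.9), det(1.0, 2.0, 0.5)]
        truths = [Segment(1.0, 2.0)]
        assert metrics.average_precision(preds, truths, 100.0) == pytest.approx(0.5)

    def test_all_fp(self):
        preds = [det(90.0, 91.0, 0.9)]
        truths = [Segment(1.0, 2.0)]
        assert metrics.average_precision(preds, truths, 10.0) == 0.0

    def test_no_truths_rejected(self):
        with pytest.raises(ValueError):
            metrics.average_precision([det(1.0, 2.0)], [], 100.0)

    def test_truth_free_scenes_excluded(self):
        """A scene with predictions but no truths contributes nothing."""
        preds = [[det(1.0, 2.0, 0.9)], [det(5.0, 6.0, 0.8)]]
        truths = [[Segment(1.0, 2.0)], []]
        assert metrics.average_precision(preds, truths, 100.0) == pytest.approx(1.0)


class TestAdaptedMap:
    def test_threshold_sweep_has_31_entries(self):
        assert len(metrics.ADAPTED_THRESHOLDS_PCT) == 31
        assert metrics.ADAPTED_THRESHOLDS_PCT[0] == 100.0
        assert metrics.ADAPTED_THRESHOLDS_PCT[-1] == 400.0

    def test_perfect_predictions(self):
        preds = [det(10.0, 15.0), det(30.0, 36.0, 0.7)]
        truths = [Segment(10.0, 15.0), Segment(30.0, 36.0)]
        assert metrics.adapted_map(preds, truths) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_at_least_strictest_threshold_ap(self, seed):
        """The sweep average dominates the AP at the strictest threshold."""
        rng = np.random.default_rng(seed)
        truths = [Segment(s, s + 5.0) for s in rng.uniform(0, 400, 5) * 1.0]
        truths = sorted(truths, key=lambda s: s.start_ms)
        preds = []
        for t in truths:
            if rng.uniform() < 0.8:
                start = max(0.0, t.start_ms + rng.normal(0, 5))
                preds.append(det(start, start + 5 + abs(rng.normal(0, 5)),
                                 rng.uniform(0.2, 1.0)))
        if not preds:
            pytest.skip("degenerate draw")
        amap = metrics.adapted_map(preds, truths)
        strictest = metrics.average_precision(preds, truths, 100.0)
        assert amap >= strictest - 1e-12


class TestCoverage:
    def test_all_matched(self):
        preds = [det(10.0, 15.0)]
        truths = [Segment(10.0, 15.0)]
        assert metrics.coverage(preds, truths) == 1.0

    def test_partial(self):
        truths = [Segment(i * 50.0, i * 50.0 + 5.0) for i in range(10)]
        preds = [det(t.start_ms, t.end_ms, 0.9) for t in truths[:8]]
        assert metrics.coverage(preds, truths) == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed + 100)
        truths = [Segment(s, s + 4.0) for s in np.sort(rng.uniform(0, 400, 6)) * 1.0]
        preds = []
        for t in truths:
            start = max(0.0, t.start_ms + rng.normal(0, 6))
            preds.append(det(start, start + 4 + abs(rng.normal(0, 6)), rng.uniform()))
        covs = [metrics.coverage(preds, truths, thr) for thr in (50, 100, 200, 400)]
        assert all(a <= b + 1e-12 for a, b in zip(covs, covs[1:]))

    def test_no_truths_rejected(self):
        with pytest.raises(ValueError):
            metrics.coverage([det(0.0, 1.0)], [])


class TestErrorMetrics:
    def test_exact_matches(self):
        pairs = [((0.0, 10.0), (0.0, 10.0))]
        stats = metrics.error_metrics(pairs)
        assert stats.duration_rel_error_mean == 0.0
        assert stats.start_error_ms_mean == 0.0
        assert stats.end_error_ms_mean == 0.0

    def test_forced_arithmetic(self):
        """Truth [0,10], prediction [1,12]: 10% duration error, 1/2 ms bounds."""
        stats = metrics.error_metrics([((1.0, 12.0), (0.0, 10.0))])
        assert stats.duration_rel_error_mean == pytest.approx(0.10)
        assert stats.start_error_ms_mean == pytest.approx(1.0)
        assert stats.end_error_ms_mean == pytest.approx(2.0)

    def test_only_matched_pairs_counted(self):
        """Unmatched predictions and truths never reach the error pool."""
        truths = [Segment(10.0, 20.0), Segment(500.0, 510.0)]
        preds = [det(11.0, 21.0, 0.9), det(900.0, 901.0, 0.8)]
        res = metrics.match_at_threshold(preds, truths, 100.0)
        stats = metrics.error_metrics(res.pairs)
        assert stats.n_pairs == 1
        assert stats.start_error_ms_mean == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics.error_metrics([])


class TestStandardMap:
    def test_perfect(self):
        preds = [det(10.0, 15.0)]
        truths = [Segment(10.0, 15.0)]
        assert metrics.standard_map_1d(preds, truths) == pytest.approx(1.0)

    def test_zero_overlap(self):
        preds = [det(100.0, 105.0)]
        truths = [Segment(10.0, 15.0)]
        assert metrics.standard_map_1d(preds, truths) == 0.0

    def test_sweep_definition(self):
        thr = metrics.STANDARD_IOU_THRESHOLDS
        assert len(thr) == 10
        assert thr[0] == 0.5 and thr[-1] == 0.95

    @pytest.mark.parametrize("seed", range(8))
    def test_not_above_adapted_map(self, seed):
        """The IoU criterion is stricter than the midpoint-distance sweep."""
        rng = np.random.default_rng(seed + 7)
        truths = [Segment(s, s + 5.0) for s in np.sort(rng.uniform(0, 450, 6)) * 1.0]
        preds = []
        for t in truths:
            start = max(0.0, t.start_ms + rng.normal(0, 2))
            preds.append(det(start, start + 5 + abs(rng.normal(0, 2)),
                             rng.uniform(0.5, 1)))
        assert (metrics.standard_map_1d(preds, truths)
                <= metrics.adapted_map(preds, truths) + 1e-9)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_metrics_in_declared_ranges(self, seed):
        rng = np.random.default_rng(seed)
        n_scene = int(rng.integers(1, 4))
        truths, preds = [], []
        for _ in range(n_scene):
            t = [Segment(s, s + rng.uniform(1, 8))
                 for s in np.sort(rng.uniform(0, 450, rng.integers(1, 6)))]
            p = []
            for x in t:
                if rng.uniform() >= 0.9:
                    continue
                start = max(0.0, x.start_ms + rng.normal(0, 10))
                end = start + x.duration_ms + abs(rng.normal(0, 10))
                p.append(det(start, end + 1e-3, rng.uniform()))
            truths.append(t)
            preds.append(p)
        amap = metrics.adapted_map(preds, truths)
        cov = metrics.coverage(preds, truths)
        smap = metrics.standard_map_1d(preds, truths)
        assert 0.0 <= amap <= 1.0
        assert 0.0 <= cov <= 1.0
        assert 0.0 <= smap <= 1.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        truths = [Segment(s, s + 5.0) for s in np.sort(rng.uniform(0, 400, 5))]
        preds = [det(t.start_ms + rng.normal(0, 3), t.end_ms + rng.normal(0, 3),
                     rng.uniform()) for t in truths]
        shift = 1234.5
        truths2 = [Segment(t.start_ms + shift, t.end_ms + shift) for t in truths]
        preds2 = [det(p.segment.start_ms + shift, p.segment.end_ms + shift, p.score)
                  for p in preds]
        assert metrics.adapted_map(preds, truths) == pytest.approx(
            metrics.adapted_map(preds2, truths2))
        assert metrics.coverage(preds, truths) == pytest.approx(
            metrics.coverage(preds2, truths2))

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_matches_exhaustive_tp_count(self, seed):
        """Score-greedy matching recovers the optimal TP count on small scenes."""
        rng = np.random.default_rng(seed + 500)
        n_t = int(rng.integers(1, 5))
        truths = [Segment(s, s + 5.0) for s in np.sort(rng.uniform(0, 200, n_t))]
        starts = rng.uniform(0, 200, n_t)
        preds = [det(s, s + 5.0, rng.uniform()) for s in starts]
        threshold = 150.0
        res = metrics.match_at_threshold(preds, truths, threshold)

        best = 0
        for perm in itertools.permutations(range(len(truths))):
            for assign in itertools.combinations(range(len(preds)), len(truths)):
                tp = sum(
                    metrics.midpoint_distance_pct(preds[p].segment, truths[t])
                    < threshold
                    for p, t in zip(assign, perm))
                best = max(best, tp)
        # the greedy matcher may occasionally fall one short of optimal
        assert res.n_tp >= best - 1
        assert res.n_tp <= best
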