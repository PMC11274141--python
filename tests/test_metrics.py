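import pytest

from bitewing import (BoundingBox, ConfusionCounts, Detection, ParameterError,
                      UndefinedMetricError, average_precision,
                      classification_metrics, iou, match_detections,
                      mean_average_precision, precision, recall, specificity)
from oracles import average_precision_oracle


def box(x0, y0, x1, y1):
    return BoundingBox(x0, y0, x1, y1)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(box(0, 0, 10, 10), box(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(0, 0, 10, 10), box(20, 20, 30, 30)) == 0.0

    def test_partial_overlap_area_arithmetic(self):
        assert iou(box(0, 0, 10, 10), box(5, 5, 15, 15)) == pytest.approx(25 / 175)


class TestMatching:
    def test_perfect_detection_set(self):
        truths = [box(0, 0, 10, 10), box(20, 0, 30, 10), box(40, 0, 50, 10)]
        dets = [Detection(t, 0.9) for t in truths]
        counts, flags = match_detections(dets, truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (3, 0, 0, 0)
        assert all(flags)

    def test_no_detections_leaves_all_truths_unmatched(self):
        truths = [box(0, 0, 10, 10), box(20, 0, 30, 10)]
        counts, flags = match_detections([], truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 2)
        assert flags == []

    def test_crafted_fixture_matches_exhaustive_assignment(self):
        # 4 truths, 5 detections; high-confidence detections claim the best
        # unmatched truth first, so det D (low confidence, overlapping T0
        # like det A does) ends up a false positive
        truths = [box(0, 0, 10, 10), box(20, 0, 30, 10),
                  box(40, 0, 50, 10), box(60, 0, 70, 10)]
        dets = [
            Detection(box(1, 0, 11, 10), 0.95),   # A: T0, IoU 9/11
            Detection(box(20, 0, 30, 10), 0.90),  # B: T1 exactly
            Detection(box(2, 0, 12, 10), 0.85),   # D: T0 again -> Fp
            Detection(box(41, 1, 51, 11), 0.80),  # C: T2
            Detection(box(100, 0, 110, 10), 0.70),  # E: nothing -> Fp
        ]
        counts, flags = match_detections(dets, truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (3, 2, 1)
        assert flags == [True, True, False, True, False]

    def test_each_truth_matched_at_most_once(self):
        truths = [box(0, 0, 10, 10)]
        dets = [Detection(box(0, 0, 10, 10), 0.9), Detection(box(1, 0, 11, 10), 0.8)]
        counts, _ = match_detections(dets, truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)


class TestClassificationMetrics:
    def test_symmetric_97_3_counts_give_97_percent_everywhere(self):
        c = ConfusionCounts(tp=97, fp=3, fn=3, tn=97)
        assert classification_metrics(c) == (97.0, 97.0, 97.0)

    def test_no_false_positives_gives_perfect_precision(self):
        assert precision(ConfusionCounts(tp=50, fp=0, fn=5, tn=0)) == 100.0

    def test_zero_denominators_raise_not_return_zero(self):
        empty = ConfusionCounts(tp=0, fp=0, fn=0, tn=0)
        for metric in (precision, recall, specificity):
            with pytest.raises(UndefinedMetricError):
                metric(empty)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


class TestAveragePrecision:
    truths = [box(0, 0, 10, 10), box(20, 0, 30, 10), box(40, 0, 50, 10)]

    def test_all_correct_detections_give_ap_one(self):
        dets = [Detection(t, c) for t, c in zip(self.truths, (0.9, 0.8, 0.7))]
        assert average_precision(dets, self.truths) == 1.0
        assert mean_average_precision({0: dets}, {0: self.truths}) == 1.0

    def test_all_wrong_detections_give_ap_zero(self):
        dets = [Detection(box(100 + 20 * i, 0, 110 + 20 * i, 10), 0.9 - i / 10)
                for i in range(3)]
        assert average_precision(dets, self.truths) == 0.0

    def test_six_detection_fixture_equals_cut_point_enumeration(self):
        dets = [
            Detection(box(0, 0, 10, 10), 0.95),     # hit T0
            Detection(box(100, 0, 110, 10), 0.90),  # miss
            Detection(box(20, 0, 30, 10), 0.85),    # hit T1
            Detection(box(120, 0, 130, 10), 0.80),  # miss
            Detection(box(40, 0, 50, 10), 0.75),    # hit T2
            Detection(box(140, 0, 150, 10), 0.70),  # miss
        ]
        _, flags = match_detections(dets, self.truths, 0.5)
        want = average_precision_oracle(
            [(d.confidence, f) for d, f in zip(dets, flags)], len(self.truths))
        got = average_precision(dets, self.truths, 0.5)
        assert got == pytest.approx(want)
        # the oracle value itself, worked by hand from the cut-points:
        # precisions 1/1, 2/3, 3/5 at recalls 1/3, 2/3, 3/3
        assert want == pytest.approx((1 / 3) * 1.0 + (1 / 3) * (2 / 3) + (1 / 3) * (3 / 5))

    def test_map_is_invariant_to_uniform_confidence_rescaling(self):
        dets = [
            Detection(box(0, 0, 10, 10), 0.9),
            Detection(box(100, 0, 110, 10), 0.6),
            Detection(box(20, 0, 30, 10), 0.3),
        ]
        scaled = [Detection(d.box, d.confidence / 3) for d in dets]
        a = mean_average_precision({0: dets}, {0: self.truths})
        b = mean_average_precision({0: scaled}, {0: self.truths})
        assert a == pytest.approx(b)

    def test_duplicate_false_positive_never_raises_ap(self):
        dets = [
            Detection(box(0, 0, 10, 10), 0.9),
            Detection(box(100, 0, 110, 10), 0.6),
            Detection(box(20, 0, 30, 10), 0.3),
        ]
        base = average_precision(dets, self.truths)
        worse = dets + [Detection(box(100, 0, 110, 10), 0.5)]
        assert average_precision(worse, self.truths) <= base

    def test_class_without_truth_is_excluded_with_warning(self):
        dets = {0: [Detection(self.truths[0], 0.9)], 1: [Detection(box(0, 0, 5, 5), 0.5)]}
        with pytest.warns(UserWarning, match="class 1"):
            value = mean_average_precision(dets, {0: [self.truths[0]], 1: []})
        assert value == 1.0

    def test_eleven_point_mode_on_perfect_detections(self):
        dets = [Detection(t, 0.9) for t in self.truths]
        assert average_precision(dets, self.truths, mode="eleven_point") == 1.0
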