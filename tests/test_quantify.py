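"""Windowed-mode quantification: cadence formula, modal reduction, Similarity, Cthr2 sweep."""

import math

import numpy as np
import pytest

from jellyquant import (
    BoundingBox,
    CountTimeline,
    Detection,
    DetectionStream,
    InformationPoint,
    WindowConfig,
    cthr2_sweep,
    equivalent_window_size,
    quantify,
    similarity,
    stream_to_information_points,
    t_r_i_point,
    window_reduce,
)

A, B = "Pelagia noctiluca", "Rhizostoma pulmo"


def points_from_counts(counts, classes=(A,), fps=1.0):
    """Information points with frame ids 0..N-1 from per-class count lists."""
    n = len(next(iter(counts.values()))) if isinstance(counts, dict) else len(counts)
    if not isinstance(counts, dict):
        counts = {classes[0]: counts}
    return [
        InformationPoint(frame_id=i, time=i / fps, counts={c: counts[c][i] for c in counts})
        for i in range(n)
    ]


def timeline_from_counts(counts, classes=(A,)):
    if not isinstance(counts, dict):
        counts = {classes[0]: counts}
    n = len(next(iter(counts.values())))
    cls = tuple(counts)
    return CountTimeline(
        classes=cls, entries=[(i, {c: counts[c][i] for c in cls}) for i in range(n)]
    )


def stream_from_frames(frames, fps=1.6):
    return DetectionStream(fps=fps, frames=frames)


def det(frame, conf, label=A, x=0.0):
    return Detection(frame, label, conf, BoundingBox(x, 0, x + 10, 10))


class TestCadence:
    @pytest.mark.parametrize(
        "w_size, w_overlap, fps, expected",
        [
            (8, 0.25, 1.6, 3.75),
            (12, 0.25, 1.6, 5.625),  # printed as 5.62 after truncation
            (4, 0.25, 1.6, 1.875),
            (10, 0.0, 2.0, 5.0),  # zero-overlap limit: W/fps
        ],
    )
    def test_known_values(self, w_size, w_overlap, fps, expected):
        assert t_r_i_point(w_size, w_overlap, fps) == pytest.approx(expected)

    def test_fps_must_be_positive(self):
        with pytest.raises(ValueError):
            t_r_i_point(8, 0.25, 0.0)


class TestEquivalentWindowSize:
    @pytest.mark.parametrize(
        "fps, target, overlap, expected",
        [
            (25.2, 1.875, 0.25, 63),
            (10.0, 1.875, 0.25, 25),
            (25.2, 3.75, 0.25, 126),
            (25.2, 5.625, 0.25, 189),
            (10.0, 5.625, 0.25, 75),
        ],
    )
    def test_preserves_cadence_across_detector_speeds(self, fps, target, overlap, expected):
        w = equivalent_window_size(fps, target, overlap)
        assert w == expected
        assert t_r_i_point(w, overlap, fps) == pytest.approx(target)

    @pytest.mark.parametrize("w, fps", [(4, 1.6), (12, 1.6), (25, 10.0)])
    def test_self_inversion(self, w, fps):
        assert equivalent_window_size(fps, t_r_i_point(w, 0.0, fps), 0.0) == w

    def test_non_integer_result_reports_neighbours(self):
        with pytest.raises(ValueError, match="2 and 3"):
            equivalent_window_size(1.0, 2.5, 0.0)


class TestWindowConfig:
    def test_stride_values_for_standard_grid(self):
        strides = {
            (w, o): WindowConfig(w, o).stride
            for w in (4, 8, 12)
            for o in (0.25, 0.5, 0.75)
        }
        assert strides[(4, 0.75)] == 1 and strides[(4, 0.5)] == 2 and strides[(4, 0.25)] == 3
        assert strides[(12, 0.25)] == 9 and strides[(12, 0.5)] == 6 and strides[(12, 0.75)] == 3

    def test_non_integer_stride_rejected(self):
        with pytest.raises(ValueError, match="non-integer stride"):
            WindowConfig(w_size=5, w_overlap=0.25)

    def test_overlap_must_leave_positive_stride(self):
        with pytest.raises(ValueError):
            WindowConfig(w_size=1, w_overlap=0.5)


class TestStreamToInformationPoints:
    def test_cutoff_removes_low_confidence_counts(self):
        stream = stream_from_frames(
            [(0, [det(0, 0.9), det(0, 0.8), det(0, 0.3, label=B)])]
        )
        pts = stream_to_information_points(stream, cthr2=50, classes=(A, B))
        assert pts[0].counts == {A: 2, B: 0}

    def test_zero_cutoff_gives_raw_counts(self):
        stream = stream_from_frames([(0, [det(0, 0.01), det(0, 0.99)])])
        pts = stream_to_information_points(stream, cthr2=0, classes=(A,))
        assert pts[0].counts == {A: 2}

    def test_empty_frame_is_all_zero(self):
        stream = stream_from_frames([(3, [])])
        pts = stream_to_information_points(stream, classes=(A, B))
        assert pts == [InformationPoint(3, 3 / 1.6, {A: 0, B: 0})]

    def test_timestamps_follow_analysis_rate(self):
        stream = stream_from_frames([(0, []), (4, []), (8, [])], fps=2.0)
        assert [p.time for p in stream_to_information_points(stream, classes=(A,))] == [0.0, 2.0, 4.0]


class TestWindowReduce:
    def test_constant_stream_is_preserved(self):
        pts = points_from_counts([3] * 10)
        out = window_reduce(pts, WindowConfig(4, 0.5))
        assert [p.counts[A] for p in out] == [3, 3, 3, 3]

    def test_single_outlier_is_suppressed(self):
        # hand-enumerated windows of 4 with 50% overlap over [1,1,1,2,1,1,1,1]:
        # {1,1,1,2} -> 1, {1,2,1,1} -> 1, {1,1,1,1} -> 1
        pts = points_from_counts([1, 1, 1, 2, 1, 1, 1, 1])
        out = window_reduce(pts, WindowConfig(4, 0.5))
        assert [p.counts[A] for p in out] == [1, 1, 1]

    def test_resulting_point_count_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(12, 200))
            w, o = [(4, 0.5), (12, 0.25), (8, 0.75)][int(rng.integers(3))]
            cfg = WindowConfig(w, o)
            pts = points_from_counts(list(rng.integers(0, 3, n)))
            out = window_reduce(pts, cfg)
            assert len(out) == (n - w) // cfg.stride + 1

    def test_stamped_at_window_final_frame(self):
        pts = points_from_counts([0] * 8)
        out = window_reduce(pts, WindowConfig(4, 0.5))
        assert [p.frame_id for p in out] == [3, 5, 7]

    def test_cadence_matches_frame_gaps(self):
        fps = 1.6
        cfg = WindowConfig(12, 0.25)
        pts = points_from_counts([1] * 60, fps=fps)
        out = window_reduce(pts, cfg)
        gaps = {round((b.frame_id - a.frame_id) / fps, 9) for a, b in zip(out, out[1:])}
        assert gaps == {round(t_r_i_point(12, 0.25, fps), 9)}

    def test_mode_is_per_class(self):
        # class A flickers up while B flickers down in different frames;
        # each class recovers its own majority value
        counts = {A: [1, 1, 2, 1], B: [0, 1, 0, 0]}
        pts = points_from_counts(counts, classes=(A, B))
        out = window_reduce(pts, WindowConfig(4, 0.25))
        assert out[0].counts == {A: 1, B: 0}

    def test_tie_breaks_toward_previous_then_lower(self):
        # first window ties 1 vs 2 with no previous value -> lower count wins;
        # second window ties again but now 1 is the previous value
        pts = points_from_counts([1, 2, 1, 2, 1, 2])
        out = window_reduce(pts, WindowConfig(2, 0.0))
        assert [p.counts[A] for p in out] == [1, 1, 1]

    def test_short_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no output"):
            assert window_reduce(points_from_counts([1, 2]), WindowConfig(4)) == []

    def test_modal_majority_suppresses_sporadic_errors(self):
        # fewer than ceil(w_size/2) corrupted points in every window leave
        # every resulting point at the true count
        rng = np.random.default_rng(37)
        for w_size, w_overlap in [(4, 0.5), (8, 0.25), (12, 0.25)]:
            cfg = WindowConfig(w_size, w_overlap)
            n = 120
            true_count = 1
            counts = [true_count] * n
            budget = math.ceil(w_size / 2) - 1
            # corrupt `budget` consecutive points every 2*w_size positions, so
            # any window of w_size points sees at most `budget` deviations
            for start in range(0, n - budget, 2 * w_size):
                for j in range(budget):
                    counts[start + j] = int(rng.choice([0, 2, 3]))
            out = window_reduce(points_from_counts(counts), cfg)
            assert all(p.counts[A] == true_count for p in out)


class TestSimilarity:
    def test_equal_predictions_give_hundred_percent(self):
        tl = timeline_from_counts([1, 1, 2, 2])
        assert similarity(points_from_counts([1, 1, 2, 2]), tl) == 100.0

    def test_three_of_four_correct(self):
        tl = timeline_from_counts([1, 1, 1, 1])
        assert similarity(points_from_counts([1, 1, 1, 0]), tl) == 75.0

    def test_full_vector_must_match(self):
        tl = timeline_from_counts({A: [1], B: [1]}, classes=(A, B))
        pred = points_from_counts({A: [1], B: [0]}, classes=(A, B))
        assert similarity(pred, tl) == 0.0

    def test_empty_prediction_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            similarity([], timeline_from_counts([1]))

    def test_missing_truth_frame_rejected(self):
        tl = timeline_from_counts([1, 1])
        with pytest.raises(ValueError, match="absent"):
            similarity([InformationPoint(9, 9.0, {A: 1})], tl)

    def test_matches_pointwise_comparison_oracle(self):
        rng = np.random.default_rng(41)
        truth_counts = list(rng.integers(0, 3, 50))
        pred_counts = [
            c if rng.random() > 0.3 else int(rng.integers(0, 3)) for c in truth_counts
        ]
        tl = timeline_from_counts(truth_counts)
        pred = points_from_counts(pred_counts)
        expected = 100.0 * sum(a == b for a, b in zip(pred_counts, truth_counts)) / 50
        assert similarity(pred, tl) == pytest.approx(expected)


class TestCthr2Sweep:
    def _stream_with_separated_confidences(self, n=40):
        """One true animal per frame at confidence 0.9, a same-class spurious
        box at 0.10 in every frame."""
        frames = [
            (i, [det(i, 0.9), det(i, 0.10, x=200.0)]) for i in range(n)
        ]
        return stream_from_frames(frames, fps=1.0), timeline_from_counts([1] * n)

    def test_best_cutoff_is_lowest_that_removes_false_positives(self):
        stream, truth = self._stream_with_separated_confidences()
        entry = cthr2_sweep(stream, truth, [WindowConfig(1)], classes=(A,))[0]
        # cutoffs 0-10% keep the 0.10 spurious box (count 2 everywhere);
        # 11% is the lowest cutoff reaching Similarity 100%
        assert entry.best_similarity == 100.0
        assert entry.best_cthr2 == 11

    def test_clean_stream_best_at_zero(self):
        n = 20
        frames = [(i, [det(i, 0.9)]) for i in range(n)]
        stream = stream_from_frames(frames, fps=1.0)
        entry = cthr2_sweep(stream, timeline_from_counts([1] * n), [WindowConfig(4, 0.5)], classes=(A,))[0]
        assert entry.best_cthr2 == 0 and entry.best_similarity == 100.0

    def test_empty_stream_similarity_is_share_of_zero_truth(self):
        n = 16
        frames = [(i, []) for i in range(n)]
        stream = stream_from_frames(frames, fps=1.0)
        truth = timeline_from_counts([0] * 12 + [1] * 4)
        entry = cthr2_sweep(stream, truth, [WindowConfig(1)], classes=(A,))[0]
        assert entry.best_similarity == pytest.approx(100.0 * 12 / 16)

    def test_reproduces_exhaustive_loop_oracle(self):
        rng = np.random.default_rng(43)
        n = 60
        frames = []
        truth_counts = []
        for i in range(n):
            dets = []
            c = int(rng.integers(0, 2))
            truth_counts.append(c)
            for _ in range(c):
                dets.append(det(i, float(rng.uniform(0.6, 0.99))))
            if rng.random() < 0.3:
                dets.append(det(i, float(rng.uniform(0.01, 0.4)), x=300.0))
            frames.append((i, dets))
        stream = stream_from_frames(frames, fps=1.0)
        truth = timeline_from_counts(truth_counts)
        cfg = WindowConfig(4, 0.5)
        entry = cthr2_sweep(stream, truth, [cfg], classes=(A,))[0]

        # independent exhaustive loop over all 101 cutoffs
        best_thr, best_sim = None, -1.0
        for thr in range(101):
            pts = stream_to_information_points(stream, thr, classes=(A,))
            reduced = window_reduce(pts, cfg)
            sim = similarity(reduced, truth)
            if sim > best_sim:
                best_thr, best_sim = thr, sim
        assert (entry.best_cthr2, entry.best_similarity) == (best_thr, pytest.approx(best_sim))


class TestQuantify:
    def test_no_smoothing_limit_reproduces_raw_counts(self):
        rng = np.random.default_rng(47)
        frames = []
        for i in range(30):
            frames.append((i, [det(i, float(rng.uniform(0.2, 0.99)), x=50.0 * k) for k in range(rng.integers(0, 3))]))
        stream = stream_from_frames(frames)
        res = quantify(stream, WindowConfig(1, 0.0, 0.0), classes=(A,), apply_nms=False)
        raw = stream_to_information_points(stream, 0, classes=(A,))
        assert res.resulting_points == raw

    def test_composition_equals_stagewise_calls(self):
        rng = np.random.default_rng(53)
        frames = [
            (i, [det(i, float(rng.uniform(0, 1)), x=60.0 * k) for k in range(rng.integers(0, 4))])
            for i in range(40)
        ]
        stream = stream_from_frames(frames, fps=1.6)
        cfg = WindowConfig(12, 0.25, cthr2=20)
        res = quantify(stream, cfg, classes=(A,), apply_nms=False)
        staged = window_reduce(stream_to_information_points(stream, 20, classes=(A,)), cfg)
        assert res.resulting_points == staged
        assert res.t_r_i_point == pytest.approx(5.625)

    def test_similarity_populated_with_truth(self):
        frames = [(i, [det(i, 0.9)]) for i in range(12)]
        stream = stream_from_frames(frames, fps=1.0)
        truth = timeline_from_counts([1] * 12)
        res = quantify(stream, WindowConfig(4, 0.5), truth=truth, classes=(A,))
        assert res.similarity == 100.0

    def test_monotone_stability_in_window_size(self):
        # with piecewise-constant truth and i.i.d. sporadic errors, larger
        # windows never hurt expected Similarity
        n, p_err = 120, 0.15
        reps = 200
        means = {}
        for w in (4, 8, 12):
            cfg = WindowConfig(w, 0.5)
            sims = []
            for rep in range(reps):
                rng = np.random.default_rng(1000 + rep)
                counts = [
                    1 if rng.random() > p_err else int(rng.choice([0, 2]))
                    for _ in range(n)
                ]
                out = window_reduce(points_from_counts(counts), cfg)
                sims.append(
                    similarity(out, timeline_from_counts([1] * n))
                )
            means[w] = np.mean(sims)
        assert means[4] <= means[8] <= means[12]
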