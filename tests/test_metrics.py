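import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsloc.io import GroundTruthAnnotation
from capsloc.localize import LocalizationResult
from capsloc.metrics import (
    UndefinedMetricError,
    ablation_reduction,
    aggregate,
    evaluate_localizations,
    nef,
    per_class_precision,
    precision,
)


class TestPrecision:
    @pytest.mark.parametrize("tp,fp,expected", [(9, 1, 0.9), (5, 0, 1.0)])
    def test_examples(self, tp, fp, expected):
        assert precision(tp, fp) == pytest.approx(expected)

    def test_no_positive_predictions_is_undefined_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            precision(0, 0)

    @given(tp=st.integers(0, 10_000), fp=st.integers(0, 10_000))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_one_iff_no_false_positives(self, tp, fp):
        if tp + fp == 0:
            return
        p = precision(tp, fp)
        assert 0.0 <= p <= 1.0
        assert (p == 1.0) == (fp == 0 and tp > 0)

    def test_per_class_matches_brute_force_frame_tally(self, rng):
        truth = rng.integers(1, 4, size=5000)
        pred = truth.copy()
        flip = rng.random(5000) < 0.1
        pred[flip] = rng.integers(1, 4, size=int(flip.sum()))
        result = per_class_precision(truth, pred)
        for c in (1, 2, 3):
            tp = fp = 0
            for t, p in zip(truth, pred):
                if p == c:
                    if t == c:
                        tp += 1
                    else:
                        fp += 1
            if tp + fp:
                assert result[c] == pytest.approx(tp / (tp + fp))


class TestNef:
    @pytest.mark.parametrize(
        "stp,optp,expected", [(1000, 1485, 485), (1000, 1000, 0)]
    )
    def test_examples(self, stp, optp, expected):
        assert nef(stp, optp) == expected

    @given(a=st.integers(0, 10**6), b=st.integers(0, 10**6))
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_nonnegative_zero_iff_equal(self, a, b):
        assert nef(a, b) == nef(b, a) >= 0
        assert (nef(a, b) == 0) == (a == b)


class TestAggregate:
    def test_even_count_median_is_central_mean(self):
        assert aggregate([100, 300]) == (200.0, 200.0)

    def test_median_robust_to_outlier(self):
        maef, mdaef = aggregate([0, 0, 900])
        assert maef == pytest.approx(300.0)
        assert mdaef == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_single_outlier_cannot_move_median(self, rng):
        base = sorted(rng.integers(0, 500, size=7).tolist())
        moved = base.copy()
        moved[-1] = 10**9
        assert aggregate(base)[1] == aggregate(moved)[1]


class TestAblationReduction:
    def test_identical_lists_give_zero(self):
        assert ablation_reduction([5, 5, 5], [5, 5, 5]) == 0

    def test_antisymmetric_under_swap(self, rng):
        a = rng.integers(0, 10**5, size=6).astype(float)
        b = rng.integers(0, 10**5, size=6).astype(float)
        assert ablation_reduction(a, b) == -ablation_reduction(b, a)

    def test_linear_in_integer_inputs(self, rng):
        a = rng.integers(0, 1000, size=6).astype(float)
        b = rng.integers(0, 1000, size=6).astype(float)
        c = rng.integers(0, 1000, size=6).astype(float)
        assert ablation_reduction(a + c, b + c) == ablation_reduction(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ablation_reduction([1, 2], [1])


class TestEvaluateLocalizations:
    @staticmethod
    def _result(vid, iss, isl):
        return LocalizationResult(
            video_id=vid,
            iss_frame=iss,
            isl_frame=isl,
            iss_window=None if iss is None else iss // 100 - 1,
            isl_window=None if isl is None else isl // 100 - 1,
        )

    def test_aggregates_match_recomputation_from_per_video(self):
        anns = [GroundTruthAnnotation(f"v{i}", 1000, 5000) for i in range(4)]
        results = [
            self._result("v0", 1100, 5200),
            self._result("v1", 900, 4900),
            self._result("v2", 1000, 5600),
            self._result("v3", 1500, 5000),
        ]
        report = evaluate_localizations(results, anns)
        iss_errors = [e[0] for e in report.per_video_nef.values()]
        isl_errors = [e[1] for e in report.per_video_nef.values()]
        assert report.maef_iss == pytest.approx(np.mean(iss_errors))
        assert report.mdaef_isl == pytest.approx(np.median(isl_errors))
        assert report.total_maef == pytest.approx(
            report.maef_iss + report.maef_isl
        )
        assert report.failures == ()

    def test_non_detections_excluded_and_flagged(self):
        anns = [GroundTruthAnnotation(f"v{i}", 1000, 5000) for i in range(2)]
        results = [
            self._result("v0", 1100, 5200),
            self._result("v1", None, 4800),
        ]
        report = evaluate_localizations(results, anns)
        assert report.failures == ("v1",)
        assert report.maef_iss == pytest.approx(100.0)  # v1 excluded
        assert report.maef_isl == pytest.approx(200.0)  # both counted

    def test_unknown_video_rejected(self):
        with pytest.raises(KeyError):
            evaluate_localizations(
                [self._result("mystery", 100, 200)],
                [GroundTruthAnnotation("v0", 10, 20)],
            )
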