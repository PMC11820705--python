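import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsloc.denoise import NCPVSeries
from capsloc.localize import (
    InsufficientDataError,
    LocalizationResult,
    OPLAParams,
    WAAVSeries,
    compute_waav,
    locate_crossing,
    locate_intersections,
    n_windows,
)

from oracles import crossing_scan

DEFAULTS = OPLAParams()


def _waav(values, was=200, wass=100):
    values = np.asarray(values, dtype=float)
    return WAAVSeries(
        values=values,
        window_starts=np.arange(values.size) * wass,
        was=was,
        wass=wass,
    )


def _ncpv(values):
    return NCPVSeries(video_id="v", values=np.asarray(values, float))


class TestComputeWaav:
    def test_window_count_and_starts(self):
        waav = compute_waav(_ncpv(np.ones(450)), DEFAULTS)
        assert len(waav) == 3
        assert waav.window_starts.tolist() == [0, 100, 200]

    def test_exactly_one_window_at_minimum_length(self):
        waav = compute_waav(_ncpv(np.ones(200)), DEFAULTS)
        assert len(waav) == 1

    def test_constant_series_gives_constant_waav(self):
        waav = compute_waav(_ncpv(np.full(1000, 2.0)), DEFAULTS)
        np.testing.assert_allclose(waav.values, 2.0)

    def test_values_are_window_means(self, rng):
        x = rng.uniform(1, 3, size=730)
        waav = compute_waav(_ncpv(x), DEFAULTS)
        for i, s in enumerate(waav.window_starts):
            assert waav.values[i] == pytest.approx(x[s : s + 200].mean())

    def test_short_series_raises_naming_minimum(self):
        with pytest.raises(InsufficientDataError, match="200"):
            compute_waav(_ncpv(np.ones(150)), DEFAULTS)

    @given(
        n=st.integers(1, 5000),
        was=st.integers(1, 500),
        wass=st.integers(1, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_window_count_closed_form(self, n, was, wass):
        if wass > was:
            return
        expected = (n - was) // wass + 1 if n >= was else 0
        assert n_windows(n, was, wass) == expected
        if expected > 0:
            params = OPLAParams(was=was, wass=wass)
            waav = compute_waav(_ncpv(np.ones(n)), params)
            assert len(waav) == expected
            # every window complete
            assert waav.window_starts[-1] + was <= n


class TestLocateCrossing:
    def test_sustained_rise_detected_at_last_subthreshold_window(self):
        waav = _waav([1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2])
        assert locate_crossing(waav, 1.35, 8) == 3

    def test_flat_series_never_crosses(self):
        assert locate_crossing(_waav([1.0] * 20), 1.35, 8) is None

    def test_single_spike_fails_continuity(self):
        waav = _waav([1, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        assert locate_crossing(waav, 1.35, 8) is None

    def test_too_few_followup_windows_means_absent(self):
        waav = _waav([1, 2, 2, 2])
        assert locate_crossing(waav, 1.35, 8) is None

    def test_search_from_skips_earlier_crossings(self):
        values = [1] * 2 + [2] * 10 + [1] * 2 + [2] * 10
        waav = _waav(values)
        first = locate_crossing(waav, 1.35, 8)
        assert first == 1
        later = locate_crossing(waav, 1.35, 8, search_from=first + 1)
        assert later == 13

    @given(
        values=st.lists(
            st.sampled_from([1.0, 1.5, 2.0, 2.5, 3.0]), min_size=1, max_size=30
        ),
        threshold=st.sampled_from([1.35, 1.75, 2.4]),
        continuity=st.integers(1, 8),
        search_from=st.integers(0, 5),
    )
    @settings(max_examples=500, derandomize=True)
    def test_matches_exhaustive_scan_oracle(
        self, values, threshold, continuity, search_from
    ):
        waav = _waav(values)
        assert locate_crossing(waav, threshold, continuity, search_from) == (
            crossing_scan(values, threshold, continuity, search_from)
        )


class TestLocateIntersections:
    def test_three_level_staircase_recovers_both_boundaries(self):
        x = np.concatenate(
            [np.full(1000, 1.0), np.full(2000, 2.0), np.full(2000, 3.0)]
        )
        res = locate_intersections(_ncpv(x), DEFAULTS)
        assert res.iss_frame is not None and res.isl_frame is not None
        assert abs(res.iss_frame - 1000) <= DEFAULTS.was
        assert abs(res.isl_frame - 3000) <= DEFAULTS.was

    def test_constant_series_detects_nothing(self):
        res = locate_intersections(_ncpv(np.full(3000, 2.0)), DEFAULTS)
        assert res.iss_frame is None and res.isl_frame is None

    def test_minimum_length_stream_detects_nothing(self):
        res = locate_intersections(_ncpv(np.full(200, 1.0)), DEFAULTS)
        assert res.iss_frame is None and res.isl_frame is None

    def test_ordering_enforced_when_both_detected(self):
        x = np.concatenate(
            [np.full(1500, 1.0), np.full(2500, 2.0), np.full(2000, 3.0)]
        )
        res = locate_intersections(_ncpv(x), DEFAULTS)
        assert res.iss_frame < res.isl_frame

    def test_shift_equivariance_under_prepended_stomach(self):
        base = np.concatenate(
            [np.full(1200, 1.0), np.full(2400, 2.0), np.full(2000, 3.0)]
        )
        res0 = locate_intersections(_ncpv(base), DEFAULTS)
        k = 7
        shifted = np.concatenate([np.full(k * DEFAULTS.wass, 1.0), base])
        res1 = locate_intersections(_ncpv(shifted), DEFAULTS)
        assert res1.iss_frame == res0.iss_frame + k * DEFAULTS.wass
        assert res1.isl_frame == res0.isl_frame + k * DEFAULTS.wass

    def test_seconds_reported_only_with_fps(self):
        x = np.concatenate(
            [np.full(1200, 1.0), np.full(2400, 2.0), np.full(2000, 3.0)]
        )
        res = locate_intersections(_ncpv(x), DEFAULTS)
        assert res.iss_seconds is None
        res_fps = locate_intersections(_ncpv(x), DEFAULTS, fps=30.0)
        assert res_fps.iss_seconds == pytest.approx(res_fps.iss_frame / 30.0)

    def test_center_reporting_offsets_by_half_window(self):
        x = np.concatenate(
            [np.full(1200, 1.0), np.full(2400, 2.0), np.full(2000, 3.0)]
        )
        start = locate_intersections(_ncpv(x), DEFAULTS)
        center = locate_intersections(
            _ncpv(x), OPLAParams(report="center")
        )
        assert center.iss_frame == start.iss_frame + DEFAULTS.was // 2


class TestResultAndParams:
    def test_result_ordering_invariant(self):
        with pytest.raises(ValueError, match="precede"):
            LocalizationResult(
                video_id="v", iss_frame=500, isl_frame=400,
                iss_window=4, isl_window=3,
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OPLAParams(wass=300)
        with pytest.raises(ValueError):
            OPLAParams(st=2.5, lt=2.4)
        with pytest.raises(ValueError):
            OPLAParams(sct=0)
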