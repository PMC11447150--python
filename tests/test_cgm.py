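"""Trace loading, grid regularisation, episode detection, glycaemic summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypodiary.cgm import (
    GlucoseTrace,
    detect_sdh_episodes,
    glycaemic_summary,
    read_traces,
    regularize,
)
from hypodiary.errors import (
    ConfigurationError,
    ContractViolation,
    UndefinedStatisticError,
)
from conftest import T0, make_regular
from oracles import brute_force_episodes, episode_index_tuples


def _write_trace_csv(path, rows):
    pd.DataFrame(rows, columns=["participant_id", "timestamp", "glucose"]).to_csv(
        path, index=False
    )


class TestReadTraces:
    def test_identity_load(self, tmp_path):
        p = tmp_path / "g.csv"
        _write_trace_csv(
            p,
            [
                ("A", "2023-03-06T00:00:00", 5.0),
                ("A", "2023-03-06T00:05:00", 5.5),
                ("A", "2023-03-06T00:10:00", 6.0),
            ],
        )
        traces, report = read_traces(p)
        assert list(traces) == ["A"] and len(traces["A"]) == 3
        assert report.n_rejected == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "g.csv"
        _write_trace_csv(
            p,
            [
                ("A", "2023-03-06T00:00:00", 5.0),
                ("A", "2023-03-06T00:05:00", -1.0),
                ("A", "not-a-time", 5.0),
                ("A", "2023-03-06T00:10:00", 6.0),
            ],
        )
        traces, report = read_traces(p)
        assert len(traces["A"]) == 2
        assert report.reasons["nonpositive_or_missing_glucose"] == 1
        assert report.reasons["unparseable_timestamp"] == 1

    def test_interleaved_participants_sorted(self, tmp_path):
        p = tmp_path / "g.csv"
        _write_trace_csv(
            p,
            [
                ("B", "2023-03-06T00:10:00", 6.0),
                ("A", "2023-03-06T00:00:00", 5.0),
                ("B", "2023-03-06T00:00:00", 7.0),
                ("A", "2023-03-06T00:05:00", 5.5),
            ],
        )
        traces, _ = read_traces(p)
        assert set(traces) == {"A", "B"}
        for t in traces.values():
            assert (t.times[1:] > t.times[:-1]).all()

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "g.csv"
        pd.DataFrame({"pid": ["A"], "when": ["2023-03-06"], "glucose": [5.0]}).to_csv(
            p, index=False
        )
        with pytest.raises(ConfigurationError, match="participant"):
            read_traces(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "g.csv"
        _write_trace_csv(p, [])
        with pytest.warns(UserWarning, match="no rows"):
            traces, _ = read_traces(p)
        assert traces == {}


class TestRegularize:
    def test_exact_ticks_unchanged(self):
        times = pd.date_range(T0, periods=12, freq="5min")
        trace = GlucoseTrace("P", times, np.full(12, 5.0))
        rt = regularize(trace)
        assert rt.n_missing == 0 and len(rt) == 12
        assert (rt.glucose == 5.0).all()
        assert (rt.grid == times).all()

    def test_twenty_minute_gap_flags_four_slots(self):
        # 60-min trace sampled every 5 min with samples 20:00-40:00 removed
        times = pd.date_range(T0, periods=13, freq="5min")
        keep = [i for i in range(13) if not 4 <= i <= 7]
        trace = GlucoseTrace("P", times[keep], np.full(len(keep), 5.0))
        rt = regularize(trace)
        assert rt.n_missing == 4
        assert rt.missing_mask[4:8].all()

    def test_duplicate_slot_keeps_closest(self):
        times = pd.DatetimeIndex([T0 + pd.Timedelta(seconds=s) for s in (0, 110, 300)])
        trace = GlucoseTrace("P", times, np.array([5.0, 4.0, 6.0]))
        rt = regularize(trace)
        assert rt.n_conflicts == 1
        assert rt.glucose[0] == 5.0  # offset 0 beats offset 110

    def test_halfway_sample_ties_to_earlier_slot(self):
        trace = GlucoseTrace(
            "P", pd.DatetimeIndex([T0 + pd.Timedelta(seconds=150)]), np.array([5.0])
        )
        rt = regularize(trace)
        assert rt.start == T0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_jitter_preserves_slot_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        ticks = np.sort(rng.choice(200, size=n, replace=False)) * 300
        jitter = rng.integers(-60, 61, size=n)
        glucose = rng.uniform(3.0, 12.0, size=n)
        base = GlucoseTrace(
            "P", pd.DatetimeIndex([T0 + pd.Timedelta(seconds=int(s)) for s in ticks]), glucose
        )
        jittered = GlucoseTrace(
            "P",
            pd.DatetimeIndex(
                [T0 + pd.Timedelta(seconds=int(s + j)) for s, j in zip(ticks, jitter)]
            ),
            glucose,
        )
        a, b = regularize(base), regularize(jittered)
        assert len(a) == len(b) and a.n_missing == b.n_missing
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)


class TestDetectEpisodes:
    def test_constant_normoglycaemia_no_episode(self):
        rt = make_regular(np.full(288, 5.0))
        assert detect_sdh_episodes(rt) == []

    def test_fifteen_minutes_below_is_one_episode(self):
        rt = make_regular([5.0, 5.0, 3.5, 3.5, 3.5, 5.0])
        eps = detect_sdh_episodes(rt)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.subtype == "SDH_3.9" and ep.nadir == 3.5
        assert ep.end - ep.start == pd.Timedelta(minutes=15)

    def test_ten_minutes_below_is_no_episode(self):
        rt = make_regular([5.0, 3.5, 3.5, 5.0])
        assert detect_sdh_episodes(rt) == []

    def test_unregularised_trace_rejected(self):
        trace = GlucoseTrace(
            "P", pd.date_range(T0, periods=4, freq="5min"), np.full(4, 3.0)
        )
        with pytest.raises(ContractViolation):
            detect_sdh_episodes(trace)

    def test_long_gap_breaks_run_short_gap_bridges(self):
        # 10-min gap inside a run is bridged; 15-min gap splits it
        bridged = make_regular([3.5, 3.5, np.nan, np.nan, 3.5, 3.5])
        assert len(detect_sdh_episodes(bridged)) == 1
        split = make_regular([3.5, 3.5, 3.5, np.nan, np.nan, np.nan, 3.5, 3.5, 3.5])
        eps = detect_sdh_episodes(split)
        assert len(eps) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 51))
        v = rng.uniform(2.0, 7.0, n)
        v[rng.random(n) < 0.25] = np.nan
        rt = make_regular(v)
        assert episode_index_tuples(rt, detect_sdh_episodes(rt)) == brute_force_episodes(v)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_lower_threshold_never_increases_episode_count(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(2.0, 6.0, 48)
        v[rng.random(48) < 0.2] = np.nan
        rt = make_regular(v)
        assert len(detect_sdh_episodes(rt, threshold=3.0)) <= len(
            detect_sdh_episodes(rt, threshold=3.9)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_episode_interior_below_and_flanks_at_or_above(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(2.0, 6.0, 60)
        v[rng.random(60) < 0.2] = np.nan
        rt = make_regular(v)
        for ep in detect_sdh_episodes(rt):
            assert (ep.values < 3.9).all()
            first = int((ep.times[0] - rt.start) / rt.step)
            last = int((ep.times[-1] - rt.start) / rt.step)
            if first > 0:
                assert np.isnan(v[first - 1]) or v[first - 1] >= 3.9
            if last < len(v) - 1:
                assert np.isnan(v[last + 1]) or v[last + 1] >= 3.9


class TestGlycaemicSummary:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5.0, 5.0, 5.0, 5.0], (100.0, 0.0, 0.0)),
            ([5.0, 5.0, 11.0, 11.0], (50.0, 50.0, 0.0)),
            ([3.9, 10.0, 3.9, 10.0], (100.0, 0.0, 0.0)),  # boundaries are in range
            ([3.8, 5.0, 10.1, 5.0], (50.0, 25.0, 25.0)),
        ],
    )
    def test_known_splits(self, values, expected):
        s = glycaemic_summary(np.array(values))
        assert (s.pct_in_range, s.pct_above, s.pct_below) == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_percentages_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(1.0, 20.0, int(rng.integers(1, 300)))
        s = glycaemic_summary(v)
        assert abs(s.pct_in_range + s.pct_above + s.pct_below - 100.0) < 1e-9
        assert 0 <= min(s.pct_in_range, s.pct_above, s.pct_below)

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            glycaemic_summary(np.array([np.nan, np.nan]))

    def test_ignores_missing_slots(self):
        assert glycaemic_summary(np.array([5.0, np.nan, np.nan])).pct_in_range == 100.0
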