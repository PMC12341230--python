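"""Cleaning-rule bookkeeping: coverage, excision, gaps, tiling, ECG windows."""
from datetime import datetime

import numpy as np
import pytest

from afdas.datatypes import AFIntervalSet, BeatStream, ECGRecord
from afdas.preprocessing import (bandpass_filter, check_monitoring_coverage,
                                 clean_beats, excise_af_intervals,
                                 interpolate_short_gaps, preprocess_stream,
                                 segment_raw_ecg, segment_rr_5min)
from afdas.synthetic import RRProfile, simulate_rr_series, synthesize_ecg


def make_stream(times, labels=None, start=datetime(2021, 1, 1, 9, 0)):
    times = np.asarray(times, float)
    if labels is None:
        labels = np.full(times.size, "N")
    return BeatStream(patient_id="T", times=times, labels=np.asarray(labels),
                      recording_start=start)


def regular(start_s, end_s, rr_s=0.8):
    return np.arange(start_s, end_s, rr_s)


class TestCoverage:
    def test_day_and_night_blocks_pass(self):
        # recording starts 09:00; 4 h of beats at 10:00-14:00 (t=3600..18000)
        # and 4 h at 22:00-02:00 (t=46800..61200)
        t = np.concatenate([regular(3600, 18000), regular(46800, 61200)])
        assert check_monitoring_coverage(make_stream(t))

    def test_daytime_only_fails(self):
        t = regular(3600, 18000)  # 10:00-14:00 only
        assert not check_monitoring_coverage(make_stream(t))

    def test_split_daytime_blocks_sum(self):
        # 2 h (09:00-11:00) + 1.5 h (12:00-13:30) daytime, 3 h night (21:30-00:31)
        t = np.concatenate([
            regular(0, 7200), regular(10800, 16200),
            regular(45000, 55860),
        ])
        assert check_monitoring_coverage(make_stream(t))
        # drop the 1.5-h daytime block -> only 2 h daytime -> fail
        t2 = np.concatenate([regular(0, 7200), regular(45000, 55860)])
        assert not check_monitoring_coverage(make_stream(t2))

    def test_missing_anchor_raises(self):
        s = make_stream(regular(0, 100))
        s.recording_start = None
        with pytest.raises(ValueError):
            check_monitoring_coverage(s)


class TestExcision:
    def test_buffer_extends_150s_each_side(self):
        s = make_stream(regular(0, 2000))
        af = AFIntervalSet(np.array([[600.0, 900.0]]))
        out = excise_af_intervals(s, af)
        assert not np.any((out.times >= 450.0) & (out.times < 1050.0))
        kept_outside = np.sum((s.times < 450.0) | (s.times >= 1050.0))
        assert out.n_beats == kept_outside

    def test_empty_alarm_set_identity(self):
        s = make_stream(regular(0, 100))
        out = excise_af_intervals(s, AFIntervalSet.empty())
        assert np.array_equal(out.times, s.times)

    def test_overlapping_buffered_windows_merge(self):
        s = make_stream(regular(0, 1000))
        af = AFIntervalSet(np.array([[250.0, 251.0], [300.0, 550.0]]))
        out = excise_af_intervals(s, af)
        # buffered: [100, 401) u [150, 700) -> union [100, 700)
        assert not np.any((out.times >= 100.0) & (out.times < 700.0))
        assert np.sum(out.times < 100.0) + np.sum(out.times >= 700.0) == out.n_beats

    def test_break_flag_set_after_excised_span(self):
        s = make_stream(regular(0, 2000))
        out = excise_af_intervals(s, AFIntervalSet(np.array([[600.0, 900.0]])))
        first_after = np.argmax(out.times >= 1050.0)
        assert out.break_before[first_after]


class TestCleanBeats:
    def test_o_beat_removed_with_gap_flag(self):
        s = make_stream([1, 2, 3, 4], labels=["N", "N", "O", "N"])
        out = clean_beats(s)
        assert out.n_beats == 3
        assert list(out.labels) == ["N", "N", "N"]
        assert out.break_before[2]  # gap where the O beat was

    def test_all_normal_identity(self):
        s = make_stream(regular(0, 50))
        out = clean_beats(s)
        assert out.n_beats == s.n_beats

    def test_removed_count_exact(self):
        rng = np.random.default_rng(0)
        n = 2000
        labels = np.where(rng.random(n) < 0.05, "O", "N")
        s = make_stream(np.arange(n) * 0.8, labels=labels)
        out = clean_beats(s)
        assert out.n_beats == n - int(np.sum(labels == "O"))


class TestInterpolation:
    def test_single_beat_inserted_at_midpoint(self):
        # 0.8 s RR context with a 1.6 s gap: round(1.6/0.8)-1 = 1 insertion
        t = np.concatenate([np.arange(0, 8, 0.8), [8.8 + 0.8], [8.8 + 1.6]])
        t = np.concatenate([np.arange(0, 8.01, 0.8), np.arange(9.6, 16, 0.8)])
        s = make_stream(t)
        s.break_before[np.argmax(t >= 9.6)] = True  # 1.6-s gap at 8.0 -> 9.6
        out = interpolate_short_gaps(s)
        assert out.n_beats == s.n_beats + 1
        inserted = np.setdiff1d(out.times, s.times)
        assert inserted.size == 1
        assert np.isclose(inserted[0], 8.8)
        assert not out.break_before[np.isclose(out.times, 9.6)].any()

    def test_long_gap_left_as_boundary(self):
        t = np.concatenate([np.arange(0, 8.01, 0.8), np.arange(13.0, 20, 0.8)])
        s = make_stream(t)
        gap_at = np.argmax(t >= 13.0)
        s.break_before[gap_at] = True
        out = interpolate_short_gaps(s)  # 5-s gap >= 3 s threshold
        assert out.n_beats == s.n_beats
        assert out.break_before[gap_at]

    def test_gapless_identity(self):
        s = make_stream(regular(0, 60))
        out = interpolate_short_gaps(s)
        assert np.array_equal(out.times, s.times)


class TestSegmentation:
    def test_14min_run_gives_two_segments(self):
        s = make_stream(regular(0, 14 * 60))
        segs = segment_rr_5min(s)
        assert len(segs) == 2
        for seg in segs:
            assert seg.span_s >= 300.0

    def test_merge_across_long_gap(self):
        # 4 min, a 10-s gap, 4 min -> one merged 5-min segment, rest discarded
        t = np.concatenate([regular(0, 240), regular(250, 490)])
        s = make_stream(t)
        gap_at = np.argmax(t >= 250)
        s.break_before[gap_at] = True
        segs = segment_rr_5min(s)
        assert len(segs) == 1
        assert segs[0].span_s >= 300.0

    def test_299s_record_gives_nothing(self):
        s = make_stream(regular(0, 299))
        assert segment_rr_5min(s) == []

    def test_spans_disjoint_and_conserved(self):
        s = make_stream(regular(0, 3600))
        segs = segment_rr_5min(s)
        total_covered = sum(seg.span_s for seg in segs)
        monitored = s.times[-1] - s.times[0]
        assert total_covered <= monitored + 1e-9
        # discarded tail explains the difference
        assert monitored - total_covered < 300.0 + 1.0
        starts = [seg.start_s for seg in segs]
        assert starts == sorted(starts)

    def test_hour_index_from_segment_start(self):
        s = make_stream(regular(0, 7500))
        segs = segment_rr_5min(s)
        for seg in segs:
            assert seg.hour_index == int(seg.start_s // 3600)


@pytest.fixture(scope="module")
def clean_record():
    stream = simulate_rr_series(RRProfile(noise_frac=0.02), 600 / 3600, seed=8)
    ecg = synthesize_ecg(stream, AFIntervalSet.empty(), seed=1)
    return ecg, stream


class TestRawECGSegmentation:
    def test_two_beat_window_invalid(self):
        t = np.array([0.5, 3.0, 6.0, 7.0, 8.0, 9.0])  # window 0 has 2 beats
        s = make_stream(t)
        ecg = ECGRecord(patient_id="T", fs=500.0, samples=np.zeros(5120))
        segs = segment_raw_ecg(ecg, s, AFIntervalSet.empty(), n_select=80, seed=0)
        starts = [x.start_s for x in segs]
        assert 0.0 not in starts       # 2 beats -> invalid
        assert 5.12 in starts          # 4 beats -> valid

    def test_window_with_o_beat_invalid(self):
        t = np.arange(0.4, 10.0, 0.8)
        labels = np.full(t.size, "N")
        labels[2] = "O"  # inside first window
        s = make_stream(t, labels=labels)
        ecg = ECGRecord(patient_id="T", fs=500.0, samples=np.zeros(5120))
        segs = segment_raw_ecg(ecg, s, AFIntervalSet.empty(), n_select=80, seed=0)
        assert 0.0 not in [x.start_s for x in segs]

    def test_sampling_contract(self, clean_record):
        ecg, stream = clean_record
        a = segment_raw_ecg(ecg, stream, AFIntervalSet.empty(), n_select=80, seed=3)
        b = segment_raw_ecg(ecg, stream, AFIntervalSet.empty(), n_select=80, seed=3)
        assert len(a) == 80
        assert [x.start_s for x in a] == [x.start_s for x in b]
        c = segment_raw_ecg(ecg, stream, AFIntervalSet.empty(), n_select=80, seed=4)
        assert [x.start_s for x in a] != [x.start_s for x in c]

    def test_segment_length_and_filtering(self, clean_record):
        ecg, stream = clean_record
        segs = segment_raw_ecg(ecg, stream, AFIntervalSet.empty(), n_select=5, seed=0)
        for s in segs:
            assert s.samples.size == 2560

    def test_wrong_sampling_rate_rejected(self, clean_record):
        _, stream = clean_record
        bad = ECGRecord(patient_id="T", fs=250.0, samples=np.zeros(2560))
        with pytest.raises(ValueError):
            segment_raw_ecg(bad, stream, AFIntervalSet.empty(), seed=0)

    def test_filter_near_idempotent_on_bandlimited_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20000)
        once = bandpass_filter(x)
        twice = bandpass_filter(once)
        # energy in the passband core barely changes on refiltering
        from scipy.signal import welch
        f, p1 = welch(once, fs=500.0, nperseg=2048)
        _, p2 = welch(twice, fs=500.0, nperseg=2048)
        core = (f > 2.0) & (f < 30.0)
        assert np.abs(np.log(p2[core] / p1[core])).max() < 0.1


class TestFullChain:
    def test_no_retained_beat_near_af(self, small_cohort):
        _, patients = small_cohort
        for p in patients:
            if p.af_intervals.n == 0:
                continue
            cleaned = excise_af_intervals(p.beat_stream, p.af_intervals)
            buffered = p.af_intervals.buffered(150.0)
            assert not buffered.contains(cleaned.times).any()

    def test_segment_spans_within_monitored_time(self, small_cohort):
        _, patients = small_cohort
        for p in patients[:10]:
            segs = preprocess_stream(p.beat_stream, p.af_intervals)
            total = sum(s.span_s for s in segs)
            assert total <= p.beat_stream.duration_s + 1e-6
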