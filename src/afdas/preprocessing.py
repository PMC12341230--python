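"""Beat-stream eligibility and cleaning rules.

The analysis admits a patient only if enough monitoring covers both core
daytime (09:00-18:00) and core nighttime (21:00-06:00).  Before any HRV is
computed, spans flagged as AF by the bedside monitor are excised with a
2.5-min buffer on each side, beats labelled neither N, S nor V are removed,
short gaps (< 3 s) left by beat removal are re-interpolated from the local
RR context, and the remaining data are tiled into 5-min RR segments, merging
across long gaps so that residual data before and after an interruption are
still used.  The raw-ECG branch tiles the 500 Hz trace into non-overlapping
5.12-s windows, band-pass filters them (Butterworth 0.5-50 Hz, zero-phase)
and keeps only windows with at least three beats, all labelled N/S/V.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import signal

from .datatypes import AFIntervalSet, BeatStream, ECGRecord, ECGSegment, RRSegment

#: default buffer excised before and after each AF alarm interval (2.5 min)
AF_BUFFER_S = 150.0
#: gaps shorter than this are interpolated; longer ones split segments
MAX_INTERP_GAP_S = 3.0
#: core daytime window, seconds since midnight
DAY_WINDOW = (9 * 3600.0, 18 * 3600.0)
#: core nighttime window (wraps over midnight)
NIGHT_WINDOWS = ((21 * 3600.0, 24 * 3600.0), (0.0, 6 * 3600.0))
#: minimum coverage required in each core window
MIN_COVERAGE_S = 3 * 3600.0
#: a beat-to-beat pause above this is treated as unmonitored time
MONITOR_GAP_S = 30.0

ECG_SEGMENT_S = 5.12
ECG_FS = 500.0


# ---------------------------------------------------------------------------
# Coverage check
# ---------------------------------------------------------------------------

def _monitored_intervals(stream: BeatStream, max_pause_s: float = MONITOR_GAP_S) -> np.ndarray:
    """Contiguous monitored spans [start, end) in recording seconds."""
    t = stream.times
    if t.size < 2:
        return np.empty((0, 2))
    dt = np.diff(t)
    breaks = np.flatnonzero(dt > max_pause_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    iv = np.column_stack([t[starts], t[ends]])
    return iv[iv[:, 1] > iv[:, 0]]


def _overlap_with_daily_window(iv: np.ndarray, offset_s: float,
                               window: tuple) -> float:
    """Total overlap of recording intervals with a repeating daily window.

    ``offset_s`` is the wall-clock second-of-day at recording time 0.
    """
    w0, w1 = window
    total = 0.0
    for s, e in iv:
        # walk the interval day by day in wall-clock coordinates
        ws, we = s + offset_s, e + offset_s
        day = math.floor(ws / 86400.0)
        while day * 86400.0 < we:
            lo = max(ws, day * 86400.0 + w0)
            hi = min(we, day * 86400.0 + w1)
            if hi > lo:
                total += hi - lo
            day += 1
    return total


def check_monitoring_coverage(stream: BeatStream,
                              min_coverage_s: float = MIN_COVERAGE_S) -> bool:
    """True iff >= 3 h of monitored time falls in both core windows.

    Requires the stream's wall-clock anchor; monitored time is beat coverage
    with pauses above 30 s excluded.
    """
    if stream.recording_start is None:
        raise ValueError("stream has no wall-clock recording_start anchor")
    iv = _monitored_intervals(stream)
    start = stream.recording_start
    offset = start.hour * 3600.0 + start.minute * 60.0 + start.second
    day_s = _overlap_with_daily_window(iv, offset, DAY_WINDOW)
    night_s = sum(_overlap_with_daily_window(iv, offset, w) for w in NIGHT_WINDOWS)
    return day_s >= min_coverage_s and night_s >= min_coverage_s


# ---------------------------------------------------------------------------
# AF excision and beat cleaning
# ---------------------------------------------------------------------------

def excise_af_intervals(stream: BeatStream, af: AFIntervalSet,
                        buffer_s: float = AF_BUFFER_S) -> BeatStream:
    """Remove every beat within an AF alarm interval +- the buffer.

    Buffered windows are merged when they overlap and clipped at the record
    boundaries; removals are logged as gaps.
    """
    if af.n == 0:
        return stream.copy()
    buffered = af.buffered(buffer_s)
    keep = ~buffered.contains(stream.times)
    return stream.with_beats(keep, gap_log=[tuple(x) for x in buffered.intervals])


def clean_beats(stream: BeatStream) -> BeatStream:
    """Remove all O-labelled (artefact/other) beats, leaving gaps."""
    keep = stream.labels != "O"
    if keep.all():
        return stream.copy()
    return stream.with_beats(keep)


def interpolate_short_gaps(stream: BeatStream,
                           max_gap_s: float = MAX_INTERP_GAP_S,
                           context_beats: int = 10) -> BeatStream:
    """Bridge short gaps by evenly spaced beats at the local median RR.

    For each flagged gap shorter than ``max_gap_s`` the number of inserted
    beats is ``round(gap / local_median_rr) - 1`` placed evenly; gaps at or
    above the threshold stay flagged as segment boundaries.
    """
    t = stream.times
    if t.size < 3:
        return stream.copy()
    gap_idx = np.flatnonzero(stream.break_before[1:]) + 1  # skip first-beat break
    if gap_idx.size == 0:
        return stream.copy()
    rr_all = np.diff(t)
    new_times = [t]
    new_labels = [stream.labels]
    cleared = stream.break_before.copy()
    for i in gap_idx:
        gap = t[i] - t[i - 1]
        if gap >= max_gap_s:
            continue
        # local RR context: valid RRs around the gap (exclude the gap itself)
        lo = max(i - 1 - context_beats, 0)
        hi = min(i + context_beats, rr_all.size)
        ctx = np.concatenate([rr_all[lo:i - 1], rr_all[i:hi]])
        ctx = ctx[np.isfinite(ctx) & (ctx > 0)]
        med = float(np.median(ctx)) if ctx.size else gap
        n_insert = int(round(gap / med)) - 1 if med > 0 else 0
        if n_insert > 0:
            pos = t[i - 1] + np.arange(1, n_insert + 1) * gap / (n_insert + 1)
            new_times.append(pos)
            new_labels.append(np.full(n_insert, "N", dtype="<U1"))
        cleared[i] = False
    times = np.concatenate(new_times)
    labels = np.concatenate(new_labels)
    order = np.argsort(times)
    breaks = np.concatenate([cleared] + [np.zeros(a.size, dtype=bool)
                                         for a in new_times[1:]])
    return BeatStream(
        patient_id=stream.patient_id,
        times=times[order], labels=labels[order],
        recording_start=stream.recording_start,
        break_before=breaks[order], gaps=list(stream.gaps),
    )


# ---------------------------------------------------------------------------
# 5-min RR segmentation with gap merging
# ---------------------------------------------------------------------------

def segment_rr_5min(stream: BeatStream, window_s: float = 300.0) -> list:
    """Tile the cleaned stream into 5-min RR segments, merging across gaps.

    RR data are concatenated on a *covered-time* axis that excludes gap
    time, then tiled into non-overlapping ``window_s`` windows from the
    start; a residual tail shorter than the window is discarded.  Each
    segment is tagged with the hour index (since recording start) of its
    first beat, and carries the N/S/V counts of its beats.
    """
    t = stream.times
    if t.size < 2:
        return []
    rr_s = np.diff(t)
    valid = ~stream.break_before[1:]  # rr ending at beat i+1 is valid
    idx_rr = np.flatnonzero(valid)    # rr i runs from beat i to beat i+1
    if idx_rr.size == 0:
        return []

    segments = []
    current: list = []
    span = 0.0
    for i in idx_rr:
        current.append(i)
        span += rr_s[i]
        if span >= window_s:
            sel = np.asarray(current)
            rr_sel = rr_s[sel]
            labels = stream.labels[sel + 1]
            first_beat_t = float(t[sel[0]])
            segments.append(RRSegment(
                patient_id=stream.patient_id,
                hour_index=int(first_beat_t // 3600.0),
                rr_ms=rr_sel * 1000.0,
                t_rel_s=np.cumsum(rr_sel),
                start_s=first_beat_t,
                n_normal=int(np.sum(labels == "N")),
                n_sves=int(np.sum(labels == "S")),
                n_ves=int(np.sum(labels == "V")),
                span_s=float(span),
            ))
            current, span = [], 0.0
    # residual tail (< window_s of covered time) is discarded
    return segments


def preprocess_stream(stream: BeatStream, af: AFIntervalSet,
                      buffer_s: float = AF_BUFFER_S,
                      max_gap_s: float = MAX_INTERP_GAP_S) -> list:
    """Full cleaning chain: excise AF, drop O beats, bridge short gaps, tile."""
    s = excise_af_intervals(stream, af, buffer_s)
    s = clean_beats(s)
    s = interpolate_short_gaps(s, max_gap_s)
    return segment_rr_5min(s)


# ---------------------------------------------------------------------------
# Raw-ECG segmentation
# ---------------------------------------------------------------------------

def bandpass_filter(samples: np.ndarray, fs: float = ECG_FS,
                    low_hz: float = 0.5, high_hz: float = 50.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def segment_raw_ecg(record: ECGRecord, stream: BeatStream,
                    af: AFIntervalSet,
                    n_select: int = 80,
                    seed: int | np.random.Generator = 0,
                    buffer_s: float = AF_BUFFER_S,
                    min_beats: int = 3) -> list:
    """Tile, filter and subsample valid 5.12-s raw-ECG windows.

    The record is tiled into non-overlapping 2560-sample windows (at
    500 Hz), band-pass filtered; a window is valid only if it contains at
    least three beats, none labelled O, and does not intersect a buffered
    AF interval.  ``n_select`` valid windows are drawn uniformly without
    replacement (all of them, if fewer are available).
    """
    if abs(record.fs - ECG_FS) > 1e-9:
        raise ValueError(f"expected fs = {ECG_FS} Hz, got {record.fs}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seg_len = int(round(ECG_SEGMENT_S * record.fs))
    filtered = bandpass_filter(record.samples, fs=record.fs)
    n_windows = filtered.size // seg_len
    buffered = af.buffered(buffer_s) if af.n else af

    windows = []
    for w in range(n_windows):
        t0, t1 = w * ECG_SEGMENT_S, (w + 1) * ECG_SEGMENT_S
        in_w = (stream.times >= t0) & (stream.times < t1)
        labels = stream.labels[in_w]
        valid = (labels.size >= min_beats
                 and bool(np.isin(labels, ("N", "S", "V")).all()))
        if valid and buffered.n:
            mid = buffered.contains(np.array([t0, t1 - 1e-9]))
            overlaps = bool(mid.any()) or bool(
                ((buffered.intervals[:, 0] >= t0)
                 & (buffered.intervals[:, 1] <= t1)).any())
            valid = not overlaps
        windows.append(ECGSegment(
            patient_id=record.patient_id,
            samples=filtered[w * seg_len:(w + 1) * seg_len],
            start_s=t0,
            beat_count=int(labels.size),
            beat_labels=tuple(labels.tolist()),
            valid=valid,
        ))
    valid_windows = [s for s in windows if s.valid]
    if not valid_windows:
        return []
    if len(valid_windows) <= n_select:
        return valid_windows
    idx = rng.choice(len(valid_windows), size=n_select, replace=False)
    return [valid_windows[i] for i in np.sort(idx)]
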