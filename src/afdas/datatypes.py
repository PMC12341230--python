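"""Core data containers shared across the pipeline.

The raw substrate of the whole analysis is the *beat stream*: a per-patient
sequence of R-peak times annotated with Philips-style beat labels
(N = normal, S = supraventricular extrasystole, V = ventricular extrasystole,
O = other/artefact).  Alarm metadata arrive as half-open AF intervals in
seconds from recording start.  All downstream stages (cleaning, segmentation,
HRV feature extraction, modelling) consume these containers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional

import numpy as np

BEAT_LABELS = ("N", "S", "V", "O")


# ---------------------------------------------------------------------------
# Beat streams
# ---------------------------------------------------------------------------

@dataclass
class BeatStream:
    """Timestamped, labelled heartbeat sequence for one patient.

    Parameters
    ----------
    patient_id : str
    times : ndarray of float
        Beat (R-peak) times in seconds from recording start, strictly
        increasing.
    labels : ndarray of str
        One of ``N, S, V, O`` per beat.
    recording_start : datetime
        Wall-clock time of ``t = 0``; anchors the day/night coverage rule.
    break_before : ndarray of bool
        ``break_before[i]`` marks that the RR interval ending at beat ``i``
        is invalid (start of record, or a beat/span was removed just before
        it).  The first beat always carries a break.
    gaps : list of (start_s, end_s)
        Log of spans removed or never monitored, for bookkeeping tests.
    """

    patient_id: str
    times: np.ndarray
    labels: np.ndarray
    recording_start: datetime
    break_before: Optional[np.ndarray] = None
    gaps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.times.ndim != 1 or self.times.shape != self.labels.shape:
            raise ValueError("times and labels must be 1-d and same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.labels.size and not np.isin(self.labels, BEAT_LABELS).all():
            raise ValueError(f"labels must be one of {BEAT_LABELS}")
        if self.break_before is None:
            self.break_before = np.zeros(self.times.size, dtype=bool)
            if self.times.size:
                self.break_before[0] = True
        else:
            self.break_before = np.asarray(self.break_before, dtype=bool)
            if self.break_before.shape != self.times.shape:
                raise ValueError("break_before must align with times")

    @property
    def n_beats(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_beats >= 2 else 0.0

    def rr_ms(self) -> np.ndarray:
        """RR interval (ms) ending at each beat; NaN where invalid."""
        rr = np.full(self.times.size, np.nan)
        if self.times.size >= 2:
            rr[1:] = np.diff(self.times) * 1000.0
        rr[self.break_before] = np.nan
        return rr

    def with_beats(self, keep: np.ndarray, gap_log: Optional[list] = None) -> "BeatStream":
        """Return a copy retaining only beats where ``keep`` is True.

        The first retained beat after every removed run is flagged with a
        break; removed spans are appended to the gap log.
        """
        keep = np.asarray(keep, dtype=bool)
        new_break = self.break_before.copy()
        dropped = ~keep
        if dropped.any():
            # a retained beat inherits a break if any beat between it and the
            # previously retained beat was dropped
            cum = np.concatenate([[0], np.cumsum(dropped)])
            kept_idx = np.flatnonzero(keep)
            prev_kept = np.concatenate([[-1], kept_idx[:-1]])
            n_between = cum[kept_idx] - cum[prev_kept + 1]
            new_break[kept_idx[n_between > 0]] = True
        gaps = list(self.gaps)
        if gap_log:
            gaps.extend(gap_log)
        return BeatStream(
            patient_id=self.patient_id,
            times=self.times[keep],
            labels=self.labels[keep],
            recording_start=self.recording_start,
            break_before=new_break[keep],
            gaps=gaps,
        )

    def copy(self) -> "BeatStream":
        return replace(
            self,
            times=self.times.copy(),
            labels=self.labels.copy(),
            break_before=self.break_before.copy(),
            gaps=list(self.gaps),
        )


# ---------------------------------------------------------------------------
# AF alarm intervals
# ---------------------------------------------------------------------------

@dataclass
class AFIntervalSet:
    """Normalised set of half-open ``[start_s, end_s)`` AF alarm intervals."""

    intervals: np.ndarray  # shape (k, 2)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.intervals = _normalize_intervals(iv)

    @classmethod
    def empty(cls) -> "AFIntervalSet":
        return cls(np.empty((0, 2)))

    @property
    def n(self) -> int:
        return int(self.intervals.shape[0])

    @property
    def total_duration_s(self) -> float:
        if self.n == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def buffered(self, buffer_s: float) -> "AFIntervalSet":
        """Widen every interval by ``buffer_s`` on each side (clipped at 0)."""
        if self.n == 0:
            return AFIntervalSet.empty()
        iv = self.intervals.copy()
        iv[:, 0] = np.maximum(iv[:, 0] - buffer_s, 0.0)
        iv[:, 1] = iv[:, 1] + buffer_s
        return AFIntervalSet(iv)

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any interval (half-open)."""
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for s, e in self.intervals:
            mask |= (t >= s) & (t < e)
        return mask


def _normalize_intervals(iv: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/touching half-open intervals."""
    if iv.size == 0:
        return np.empty((0, 2))
    if np.any(iv[:, 1] <= iv[:, 0]):
        raise ValueError("interval end must exceed start")
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=float)


# ---------------------------------------------------------------------------
# RR segments and raw ECG
# ---------------------------------------------------------------------------

@dataclass
class RRSegment:
    """One contiguous (after gap-merging) 5-minute RR window.

    ``rr_ms[i]`` is the interval ending at relative covered time
    ``t_rel_s[i]`` (gap time excluded, so merged segments are contiguous on
    this axis).  ``start_s`` is the recording time of the first beat.
    """

    patient_id: str
    hour_index: int
    rr_ms: np.ndarray
    t_rel_s: np.ndarray
    start_s: float
    n_normal: int
    n_sves: int
    n_ves: int
    span_s: float

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.t_rel_s = np.asarray(self.t_rel_s, dtype=float)
        if self.rr_ms.size < 2:
            raise ValueError("RRSegment needs at least 2 RR values")
        if self.span_s < 300.0 - 1e-9:
            raise ValueError("RRSegment must span at least 300 s")


@dataclass
class ECGRecord:
    """Single-lead (lead-II-like) ECG trace at a fixed sampling rate."""

    patient_id: str
    fs: float
    samples: np.ndarray  # mV
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if not np.isfinite(self.samples).all():
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ECGSegment:
    """One 5.12-s band-passed raw-ECG window (2560 samples at 500 Hz)."""

    patient_id: str
    samples: np.ndarray
    start_s: float
    beat_count: int
    beat_labels: tuple
    valid: bool

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

CLINICAL_FIELDS = (
    "age", "sex", "nihss", "mrs", "ica_stenosis_gt50", "hypertension",
    "diabetes", "heart_failure", "cad", "log_troponin", "gfr",
)


@dataclass
class ClinicalVector:
    """Admission covariates used by the clinical model and the AS5F benchmark."""

    age: float
    sex: str  # "female" | "male"
    nihss: int
    mrs: int
    ica_stenosis_gt50: bool
    hypertension: bool
    diabetes: bool
    heart_failure: bool
    cad: bool
    log_troponin: float
    gfr: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 0 <= self.nihss <= 42:
            raise ValueError("NIHSS must lie in [0, 42]")
        if not 0 <= self.mrs <= 6:
            raise ValueError("mRS must lie in [0, 6]")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in CLINICAL_FIELDS}
        d["sex"] = 1.0 if self.sex == "male" else 0.0
        for f in ("ica_stenosis_gt50", "hypertension", "diabetes",
                  "heart_failure", "cad"):
            d[f] = float(d[f])
        return d
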