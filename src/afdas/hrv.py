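"""The 19-feature HRV bank and its hourly aggregation.

Each 5-min RR segment yields one named feature vector; per patient the
vectors are averaged within clock hours (relative to recording start) and
the hourly means are averaged over the analysis window to produce one row
per patient.  The final clinical model restricts the window to the first
hour of monitoring.

Feature registry (19 active features)
-------------------------------------
time domain      : mean_rr, median_rr, sdnn, cvnn, rmssd, pnn50
frequency domain : tp (0.003-0.4 Hz), lf (0.04-0.15), hf (0.15-0.4), lf_hf
nonlinear        : dfa_alpha1 (scales 4-16), dfa_alpha2 (16-64),
                   sampen (m=2, r=0.2*SD), mse (mean SampEn, scales 1-5),
                   sd1, sd2, sd1_sd2 (Poincare)
ectopy           : s2n (SVES / normal beats), v2n (VES / normal beats)

No detrending is applied before the nonlinear metrics; detrending degrades
their reliability on RR series.  Spectral powers use the tachogram cubic-
resampled at 4 Hz and Welch's method (256-sample Hann windows, 50% overlap).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .datatypes import RRSegment

FEATURE_NAMES = (
    "mean_rr", "median_rr", "sdnn", "cvnn", "rmssd", "pnn50",
    "tp", "lf", "hf", "lf_hf",
    "dfa_alpha1", "dfa_alpha2", "sampen", "mse",
    "sd1", "sd2", "sd1_sd2",
    "s2n", "v2n",
)

RESAMPLE_HZ = 4.0
WELCH_NPERSEG = 256
TP_BAND = (0.003, 0.4)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
DFA1_SCALES = (4, 16)
DFA2_SCALES = (16, 64)
MSE_SCALES = (1, 2, 3, 4, 5)
MIN_NONLINEAR_LEN = 100


@dataclass
class HRVFeatureVector:
    """Named HRV metrics for one 5-min segment."""

    patient_id: str
    hour_index: int
    start_s: float
    features: Dict[str, float]
    missing_reasons: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")


@dataclass
class PatientFeatureRow:
    """Per-patient model input: features averaged within, then over, hours."""

    patient_id: str
    values: Dict[str, float]
    hours_used: tuple
    n_segments_used: int


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def compute_time_domain(rr_ms: np.ndarray) -> Dict[str, float]:
    """mean/median RR, SDNN (n-1), CVNN, RMSSD, pNN50."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    d = np.diff(rr)
    mean_rr = float(np.mean(rr))
    sdnn = float(np.std(rr, ddof=1))
    return {
        "mean_rr": mean_rr,
        "median_rr": float(np.median(rr)),
        "sdnn": sdnn,
        "cvnn": sdnn / mean_rr,
        "rmssd": float(np.sqrt(np.mean(d ** 2))),
        "pnn50": float(100.0 * np.sum(np.abs(d) > 50.0) / d.size),
    }


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def compute_frequency_domain(rr_ms: np.ndarray,
                             t_s: np.ndarray) -> Dict[str, float]:
    """Welch band powers of the cubic-resampled tachogram (units ms^2).

    ``t_s`` gives the (covered) time of each RR interval's end.
    """
    rr = np.asarray(rr_ms, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if rr.size < 4:
        raise ValueError("too few beats for spectral interpolation")
    cs = CubicSpline(t, rr)
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    x = cs(grid)
    nperseg = min(WELCH_NPERSEG, x.size)
    freqs, psd = signal.welch(x, fs=RESAMPLE_HZ, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2,
                              detrend="constant")
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    out = {
        "tp": _band_power(freqs, psd, TP_BAND),
        "lf": lf,
        "hf": hf,
        "lf_hf": lf / hf if hf > 0 else np.nan,
    }
    return out


# ---------------------------------------------------------------------------
# Nonlinear
# ---------------------------------------------------------------------------

def _dfa_fluctuations(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Root-mean-square detrended fluctuation at each box size."""
    y = np.cumsum(x - np.mean(x))
    fl = np.empty(scales.size)
    for k, n in enumerate(scales):
        n_boxes = y.size // n
        if n_boxes < 2:
            fl[k] = np.nan
            continue
        z = y[: n_boxes * n].reshape(n_boxes, n)
        tt = np.arange(n, dtype=float)
        # per-box linear detrend via least squares
        t_mean = tt.mean()
        t_var = np.sum((tt - t_mean) ** 2)
        slope = (z @ (tt - t_mean)) / t_var
        inter = z.mean(axis=1) - slope * t_mean
        resid = z - (inter[:, None] + slope[:, None] * tt[None, :])
        fl[k] = np.sqrt(np.mean(resid ** 2))
    return fl


def dfa_exponent(rr: np.ndarray, scale_range: tuple) -> float:
    """DFA scaling exponent: log-log slope of F(n) over the scale range."""
    lo, hi = scale_range
    scales = np.unique(np.round(np.geomspace(lo, hi, 8)).astype(int))
    scales = scales[(scales >= lo) & (scales <= hi) & (scales >= 2)]
    fl = _dfa_fluctuations(rr, scales)
    ok = np.isfinite(fl) & (fl > 0)
    if ok.sum() < 3:
        return float("nan")
    slope, _ = np.polyfit(np.log(scales[ok]), np.log(fl[ok]), 1)
    return float(slope)


def sample_entropy(x: np.ndarray, m: int = 2, r: Optional[float] = None) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev distance, self-matches excluded.

    For a constant series (zero SD) the entropy is defined as 0; if no
    template matches exist the value is NaN (undefined).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        return float("nan")
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def count_matches(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = pdist(templ, metric="chebyshev")  # pairwise, i < j
        return int(np.sum(d <= r))

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-math.log(a / b))


def multiscale_entropy(x: np.ndarray, scales: Iterable[int] = MSE_SCALES,
                       m: int = 2) -> float:
    """Mean SampEn over coarse-grained scales; r fixed at 0.2*SD(x)."""
    x = np.asarray(x, dtype=float)
    r = 0.2 * np.std(x)
    vals = []
    for s in scales:
        n = x.size // s
        if n <= m + 1:
            continue
        cg = x[: n * s].reshape(n, s).mean(axis=1)
        vals.append(sample_entropy(cg, m=m, r=r))
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def compute_nonlinear(rr_ms: np.ndarray) -> Dict[str, float]:
    """DFA alpha1/alpha2, SampEn, MSE and Poincare descriptors."""
    rr = np.asarray(rr_ms, dtype=float)
    out: Dict[str, float] = {}
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d ** 2))) if d.size else float("nan")
    sdnn = float(np.std(rr, ddof=1)) if rr.size >= 2 else float("nan")
    sd1 = rmssd / math.sqrt(2.0)
    sd2_sq = 2.0 * sdnn ** 2 - sd1 ** 2
    sd2 = math.sqrt(sd2_sq) if sd2_sq > 0 else 0.0
    out["sd1"] = sd1
    out["sd2"] = sd2
    out["sd1_sd2"] = sd1 / sd2 if sd2 > 0 else np.nan
    if rr.size < MIN_NONLINEAR_LEN:
        out.update(dfa_alpha1=np.nan, dfa_alpha2=np.nan,
                   sampen=np.nan, mse=np.nan)
        return out
    if np.std(rr) == 0:
        out.update(dfa_alpha1=np.nan, dfa_alpha2=np.nan, sampen=0.0, mse=0.0)
        return out
    out["dfa_alpha1"] = dfa_exponent(rr, DFA1_SCALES)
    out["dfa_alpha2"] = dfa_exponent(rr, DFA2_SCALES)
    out["sampen"] = sample_entropy(rr)
    out["mse"] = multiscale_entropy(rr)
    return out


def compute_ectopy_ratios(segment: RRSegment) -> Dict[str, float]:
    """S2N and V2N: extrasystole counts relative to normal beats."""
    if segment.n_normal <= 0:
        return {"s2n": np.nan, "v2n": np.nan}
    return {
        "s2n": segment.n_sves / segment.n_normal,
        "v2n": segment.n_ves / segment.n_normal,
    }


# ---------------------------------------------------------------------------
# Per-segment vector and aggregation
# ---------------------------------------------------------------------------

def compute_segment_features(segment: RRSegment) -> HRVFeatureVector:
    """All 19 features for one 5-min segment; failures become NaN."""
    feats: Dict[str, float] = {}
    reasons: Dict[str, str] = {}
    rr = segment.rr_ms
    try:
        feats.update(compute_time_domain(rr))
    except ValueError as e:
        reasons["time_domain"] = str(e)
    try:
        feats.update(compute_frequency_domain(rr, segment.t_rel_s))
    except ValueError as e:
        reasons["frequency_domain"] = str(e)
    feats.update(compute_nonlinear(rr))
    feats.update(compute_ectopy_ratios(segment))
    for name in FEATURE_NAMES:
        feats.setdefault(name, np.nan)
    return HRVFeatureVector(
        patient_id=segment.patient_id,
        hour_index=segment.hour_index,
        start_s=segment.start_s,
        features=feats,
        missing_reasons=reasons,
    )


def restrict_first_hours(vectors: List[HRVFeatureVector],
                         hours: float) -> List[HRVFeatureVector]:
    """Keep only segments starting within the first ``hours`` of recording."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    return [v for v in vectors if v.start_s < hours * 3600.0]


def hourly_aggregate(vectors: List[HRVFeatureVector],
                     window_hours: Optional[Iterable[int]] = None) -> PatientFeatureRow:
    """Mean per feature within each hour, then mean over hours.

    ``window_hours`` limits the analysis to a set of hour indices (all
    observed hours if None).  Features missing in every segment stay NaN.
    """
    if not vectors:
        raise ValueError("no feature vectors to aggregate")
    pid = vectors[0].patient_id
    if window_hours is not None:
        window = set(int(h) for h in window_hours)
        vectors = [v for v in vectors if v.hour_index in window]
        if not vectors:
            raise ValueError(f"no segments within hour window for {pid}")
    by_hour: Dict[int, list] = {}
    for v in vectors:
        by_hour.setdefault(v.hour_index, []).append(v)
    hourly = []
    with warnings.catch_warnings():
        # features missing in every segment propagate as NaN silently
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for h in sorted(by_hour):
            mat = np.array([[v.features[f] for f in FEATURE_NAMES]
                            for v in by_hour[h]], dtype=float)
            hourly.append(np.nanmean(mat, axis=0))
        overall = np.nanmean(np.vstack(hourly), axis=0)
    return PatientFeatureRow(
        patient_id=pid,
        values=dict(zip(FEATURE_NAMES, (float(x) for x in overall))),
        hours_used=tuple(sorted(by_hour)),
        n_segments_used=len(vectors),
    )


def feature_matrix(rows: List[PatientFeatureRow]) -> pd.DataFrame:
    """Patients x features DataFrame (index = patient_id, units as in registry)."""
    df = pd.DataFrame([{"patient_id": r.patient_id, **r.values} for r in rows])
    return df.set_index("patient_id")


def featurize_patient(segments: List[RRSegment],
                      first_hours: Optional[float] = None) -> Optional[PatientFeatureRow]:
    """Segments -> per-segment vectors -> aggregated row (None if no data)."""
    if first_hours is not None:
        segments = [s for s in segments if s.start_s < first_hours * 3600.0]
    if not segments:
        return None
    vectors = [compute_segment_features(s) for s in segments]
    return hourly_aggregate(vectors)
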