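"""Synthetic stroke-unit monitoring cohorts.

Real continuous-ECG-monitoring (CEM) cohorts with adjudicated atrial
fibrillation (AF) labels are not publicly shareable, so the pipeline is
exercised end-to-end on simulated patients that reproduce the statistical
structure the analysis assumes:

* sinus RR series from an integral-pulse-frequency-modulation (IPFM) model
  with low-frequency (0.04-0.15 Hz) and high-frequency (0.15-0.4 Hz)
  oscillatory modulation plus 1/f^beta broadband noise, giving controllable
  spectral and fractal ground truth;
* Philips-style beat labels (N/S/V/O) with injected supraventricular and
  ventricular extrasystoles;
* AF episodes (>= 30 s, serially uncorrelated RR) reported as half-open
  alarm intervals, plus shorter un-alarmed atrial runs in AF-prone patients;
* day/night monitoring coverage with random dropouts;
* admission covariates whose group contrasts follow the direction of the
  derivation cohort (AF patients older, higher NIHSS/mRS, more heart
  failure);
* optionally, a template-based 500 Hz lead-II-like ECG trace in which the
  P wave is suppressed during AF and atrial runs.

The AF-prone phenotype is controlled by explicit effect sizes (RMSSD ratio,
DFA alpha1 shift, SVES rate ratio, age shift, atrial-run rate); the latent
per-patient parameters are retained for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .datatypes import AFIntervalSet, BeatStream, ClinicalVector, ECGRecord

LABEL_NO_AF = "no_af"
LABEL_NDAF = "ndaf"
LABEL_KNOWN_AF = "known_af"

#: grid rate (Hz) on which the IPFM modulation signal is sampled
_IPFM_GRID_HZ = 8.0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectSizes:
    """Planted AF-prone vs control contrasts.

    The source study reports no quantitative HRV effect sizes between
    groups; these defaults are simulation choices at the level of direction
    and rough magnitude (age shift follows the derivation-cohort means,
    79.2 vs 70.9 years).
    """

    rmssd_ratio: float = 1.5          # short-term RR variability multiplier
    dfa_alpha1_shift: float = -0.15   # reduction of the short-scale DFA exponent
    sves_rate_ratio: float = 3.0      # supraventricular ectopy multiplier
    age_shift_years: float = 8.3      # mean age difference
    short_run_rate: float = 1.0       # un-alarmed atrial runs per hour

    def __post_init__(self) -> None:
        if self.rmssd_ratio <= 0 or self.sves_rate_ratio <= 0:
            raise ValueError("effect-size ratios must be positive")
        if self.dfa_alpha1_shift > 0:
            raise ValueError("dfa_alpha1_shift must be <= 0 (AF-prone lower)")
        if self.age_shift_years < 0:
            raise ValueError("age_shift_years must be >= 0")


@dataclass
class DropoutSpec:
    """Monitoring-gap model: Poisson gap onsets, lognormal gap lengths."""

    gaps_per_hour: float = 0.3
    mean_gap_s: float = 300.0
    sigma_log: float = 0.6

    def __post_init__(self) -> None:
        if self.gaps_per_hour < 0 or self.mean_gap_s <= 0:
            raise ValueError("invalid dropout specification")


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 400
    af_prevalence: float = 0.06       # newly-detected AF rate of the derivation cohort
    known_af_fraction: float = 0.0    # pre-known AF (excluded from the primary analysis)
    monitoring_hours: float = 72.0
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    sampling_rate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.af_prevalence < 1.0:
            raise ValueError("af_prevalence must lie strictly in (0, 1)")
        if self.monitoring_hours <= 0:
            raise ValueError("monitoring_hours must be positive")


@dataclass
class RRProfile:
    """Latent sinus-rhythm parameters for one patient."""

    mean_rr_ms: float = 800.0
    lf_amp: float = 0.03      # fractional LF modulation amplitude
    hf_amp: float = 0.02      # fractional HF modulation amplitude
    lf_freq_hz: float = 0.095
    hf_freq_hz: float = 0.25
    noise_frac: float = 0.025  # SD of the 1/f^beta component (fraction of mean RR)
    noise_beta: float = 1.0    # spectral slope of the broadband component

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValueError("mean RR must be positive")
        if min(self.lf_amp, self.hf_amp, self.noise_frac) < 0:
            raise ValueError("modulation amplitudes must be non-negative")


@dataclass
class SyntheticPatient:
    patient_id: str
    label: str
    beat_stream: BeatStream
    af_intervals: AFIntervalSet
    clinical: ClinicalVector
    ecg: Optional[ECGRecord] = None
    ground_truth_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label == LABEL_NO_AF and self.af_intervals.n:
            raise ValueError("no_af patients must have an empty alarm set")


# ---------------------------------------------------------------------------
# Sinus RR generation (IPFM)
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^beta on an FFT grid."""
    if n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_rr_series(profile: RRProfile, duration_h: float,
                       seed: int | np.random.Generator) -> BeatStream:
    """Generate a sinus-rhythm beat stream by IPFM.

    The instantaneous heart rate ``m(t) = (1 + modulation(t)) / mean_rr``
    is integrated on a fine grid; a beat fires whenever the integral crosses
    an integer.  With all modulation amplitudes at zero the output is an
    exactly periodic series at ``mean_rr``.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration_s = duration_h * 3600.0
    n = int(np.ceil(duration_s * _IPFM_GRID_HZ)) + 1
    t = np.arange(n) / _IPFM_GRID_HZ

    mod = np.zeros(n)
    if profile.lf_amp > 0:
        mod += profile.lf_amp * np.sin(2 * np.pi * profile.lf_freq_hz * t
                                       + rng.uniform(0, 2 * np.pi))
    if profile.hf_amp > 0:
        mod += profile.hf_amp * np.sin(2 * np.pi * profile.hf_freq_hz * t
                                       + rng.uniform(0, 2 * np.pi))
    if profile.noise_frac > 0:
        mod += profile.noise_frac * _one_over_f_noise(n, profile.noise_beta, rng)
    # keep the rate positive even under extreme noise draws
    rate = np.clip(1.0 + mod, 0.2, None) / (profile.mean_rr_ms / 1000.0)

    # cumulative integral of the rate; beats at integer crossings
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0)
                               / _IPFM_GRID_HZ])
    n_beats = int(np.floor(integral[-1]))
    ks = np.arange(1, n_beats + 1, dtype=float)
    beat_times = np.interp(ks, integral, t)
    beat_times = beat_times[beat_times < duration_s]

    labels = np.full(beat_times.size, "N", dtype="<U1")
    return BeatStream(
        patient_id="",
        times=beat_times,
        labels=labels,
        recording_start=datetime(2021, 1, 1, 12, 0, 0),
    )


# ---------------------------------------------------------------------------
# Ectopy, AF episodes, atrial runs, gaps
# ---------------------------------------------------------------------------

def inject_ectopy(stream: BeatStream, sves_rate: float, ves_rate: float,
                  seed: int | np.random.Generator,
                  prematurity: float = 0.35) -> BeatStream:
    """Convert randomly chosen beats to premature S or V beats.

    A selected beat is moved earlier by ``prematurity`` of its preceding RR
    (shortened coupling interval followed by a compensatory pause); the beat
    count is unchanged and time order preserved.
    """
    if sves_rate < 0 or ves_rate < 0:
        raise ValueError("ectopy rates must be non-negative")
    if sves_rate == 0 and ves_rate == 0:
        return stream.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = stream.copy()
    hours = max(out.duration_s, 0.0) / 3600.0
    eligible = np.flatnonzero(out.labels == "N")
    eligible = eligible[eligible >= 1]  # need a preceding RR
    for label, rate in (("S", sves_rate), ("V", ves_rate)):
        if rate <= 0 or eligible.size == 0:
            continue
        k = min(rng.poisson(rate * hours), eligible.size)
        if k == 0:
            continue
        chosen = rng.choice(eligible, size=k, replace=False)
        for i in np.sort(chosen):
            if out.labels[i] != "N":
                continue
            rr_prev = out.times[i] - out.times[i - 1]
            shifted = out.times[i] - prematurity * rr_prev
            if shifted <= out.times[i - 1]:
                continue
            out.times[i] = shifted
            out.labels[i] = label
    return out


def inject_af_episodes(stream: BeatStream, episode_rate: float,
                       seed: int | np.random.Generator,
                       mean_duration_s: float = 120.0,
                       sigma_log: float = 0.5,
                       min_duration_s: float = 30.0,
                       af_mean_rr_ms: float = 600.0,
                       af_sd_rr_ms: float = 150.0) -> tuple:
    """Replace spans of the stream with serially independent AF rhythm.

    Episode onsets are Poisson with the given hourly rate; durations are
    lognormal, floored at 30 s (the study's minimum AF event duration).
    Overlapping requested episodes are merged before replacement.  Within
    each episode RR intervals are drawn i.i.d. (no serial correlation) from
    a broad truncated-normal distribution.  Returns the modified stream and
    the AFIntervalSet covering exactly the replaced spans.
    """
    if min_duration_s < 30.0:
        raise ValueError("AF episodes must last at least 30 s")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if episode_rate <= 0 or stream.n_beats < 2:
        return stream.copy(), AFIntervalSet.empty()
    t0, t1 = stream.times[0], stream.times[-1]
    hours = (t1 - t0) / 3600.0
    n_ep = rng.poisson(episode_rate * hours)
    if n_ep == 0:
        return stream.copy(), AFIntervalSet.empty()
    mu = np.log(mean_duration_s) - sigma_log ** 2 / 2.0
    starts = rng.uniform(t0, t1, size=n_ep)
    durs = np.maximum(rng.lognormal(mu, sigma_log, size=n_ep), min_duration_s)
    ends = np.minimum(starts + durs, t1)
    ok = ends - starts >= min_duration_s
    if not ok.any():
        return stream.copy(), AFIntervalSet.empty()
    af = AFIntervalSet(np.column_stack([starts[ok], ends[ok]]))

    keep = ~af.contains(stream.times)
    new_chunks, new_labels = [], []
    for s, e in af.intervals:
        rr = rng.normal(af_mean_rr_ms, af_sd_rr_ms,
                        size=int(np.ceil((e - s) / (af_mean_rr_ms / 1000.0) * 2)) + 8)
        rr = np.clip(rr, 280.0, 1800.0) / 1000.0
        bt = s + np.cumsum(rr)
        bt = bt[bt < e]
        new_chunks.append(bt)
        new_labels.append(np.full(bt.size, "N", dtype="<U1"))
    all_times = np.concatenate([stream.times[keep]] + new_chunks)
    all_labels = np.concatenate([stream.labels[keep]] + new_labels)
    order = np.argsort(all_times)
    out = BeatStream(
        patient_id=stream.patient_id,
        times=all_times[order],
        labels=all_labels[order],
        recording_start=stream.recording_start,
        gaps=list(stream.gaps),
    )
    return out, af


def inject_atrial_runs(stream: BeatStream, run_rate: float,
                       seed: int | np.random.Generator,
                       run_beats_range: tuple = (5, 20),
                       run_rr_ms: float = 480.0,
                       run_rr_sd_ms: float = 90.0) -> tuple:
    """Insert brief (< 30 s) irregular atrial runs that raise no alarm.

    Returns the stream and the list of run ``(start, end)`` spans (used to
    suppress the P wave in synthetic ECG).  Runs emulate short atrial
    tachycardia bursts typical of the AF-prone phenotype.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if run_rate <= 0 or stream.n_beats < 10:
        return stream.copy(), []
    t0, t1 = stream.times[0], stream.times[-1]
    n_runs = rng.poisson(run_rate * (t1 - t0) / 3600.0)
    if n_runs == 0:
        return stream.copy(), []
    spans = []
    times = stream.times
    labels = stream.labels
    for _ in range(n_runs):
        nb = int(rng.integers(run_beats_range[0], run_beats_range[1] + 1))
        s = rng.uniform(t0, t1 - 30.0)
        rr = np.clip(rng.normal(run_rr_ms, run_rr_sd_ms, size=nb), 300.0, 900.0) / 1000.0
        bt = s + np.cumsum(rr)
        e = min(bt[-1] + 0.2, s + 29.0)
        bt = bt[bt < e]
        if bt.size < 3:
            continue
        keep = (times < s) | (times >= e)
        times = np.concatenate([times[keep], bt])
        lab = np.full(bt.size, "N", dtype="<U1")
        labels = np.concatenate([labels[keep], lab])
        order = np.argsort(times)
        times, labels = times[order], labels[order]
        spans.append((s, e))
    out = BeatStream(
        patient_id=stream.patient_id, times=times, labels=labels,
        recording_start=stream.recording_start, gaps=list(stream.gaps),
    )
    return out, spans


def relabel_artifacts(stream: BeatStream, o_fraction: float,
                      seed: int | np.random.Generator) -> BeatStream:
    """Relabel a random fraction of beats as O (artefact/other)."""
    if o_fraction <= 0:
        return stream.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = stream.copy()
    mask = rng.random(out.n_beats) < o_fraction
    out.labels[mask] = "O"
    return out


def insert_monitoring_gaps(stream: BeatStream, dropout: DropoutSpec,
                           seed: int | np.random.Generator) -> BeatStream:
    """Remove beats inside randomly sampled dropout windows.

    Gap onsets are Poisson (``gaps_per_hour``); lengths lognormal with the
    configured mean.  Gap windows are logged in the stream metadata.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dropout.gaps_per_hour <= 0 or stream.n_beats < 2:
        return stream.copy()
    t0, t1 = stream.times[0], stream.times[-1]
    n_gaps = rng.poisson(dropout.gaps_per_hour * (t1 - t0) / 3600.0)
    if n_gaps == 0:
        return stream.copy()
    mu = np.log(dropout.mean_gap_s) - dropout.sigma_log ** 2 / 2.0
    starts = rng.uniform(t0, t1, size=n_gaps)
    lens = rng.lognormal(mu, dropout.sigma_log, size=n_gaps)
    iv = AFIntervalSet(np.column_stack([starts, np.minimum(starts + lens, t1 + 1.0)]))
    keep = ~iv.contains(stream.times)
    return stream.with_beats(keep, gap_log=[tuple(x) for x in iv.intervals])


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

def sample_clinical_features(label: str, effect_sizes: EffectSizes,
                             seed: int | np.random.Generator) -> ClinicalVector:
    """Draw admission covariates for one patient.

    Group contrasts follow the derivation-cohort direction: AF patients are
    older (by ``age_shift_years``), have higher NIHSS and mRS and more
    heart failure; most binary comorbidities differ little.
    """
    if label not in (LABEL_NO_AF, LABEL_NDAF, LABEL_KNOWN_AF):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    af = label != LABEL_NO_AF
    age_mean = 70.9 + (effect_sizes.age_shift_years if af else 0.0)
    age_sd = 9.0 if af else 13.4
    age = float(np.clip(rng.normal(age_mean, age_sd), 35.0, 99.0))
    # NIHSS: right-skewed; gamma shapes target means ~6.7 (AF) vs ~2.9
    shape, scale = (0.8, 8.4) if af else (0.6, 4.8)
    nihss = int(np.clip(np.round(rng.gamma(shape, scale)), 0, 42))
    mrs_mean = 2.9 if af else 1.7
    mrs = int(np.clip(np.round(rng.normal(mrs_mean, 1.6)), 0, 6))
    p_female = 0.524 if af else 0.465
    sex = "female" if rng.random() < p_female else "male"
    flags = {
        "ica_stenosis_gt50": 0.049 if af else 0.063,
        "hypertension": 0.767 if af else 0.742,
        "diabetes": 0.252 if af else 0.217,
        "heart_failure": 0.155 if af else 0.083,
        "cad": 0.155 if af else 0.186,
    }
    drawn = {k: bool(rng.random() < p) for k, p in flags.items()}
    log_troponin = float(rng.normal(2.9 if af else 2.3, 0.9))
    gfr = float(np.clip(rng.normal(65.0 if af else 75.0, 20.0), 5.0, 150.0))
    return ClinicalVector(age=age, sex=sex, nihss=nihss, mrs=mrs,
                          log_troponin=log_troponin, gfr=gfr, **drawn)


# ---------------------------------------------------------------------------
# Synthetic ECG
# ---------------------------------------------------------------------------

#: (amplitude mV, width s, offset s from R peak); P listed separately
_QRST_WAVES = (
    (-0.10, 0.010, -0.030),   # Q
    (1.00, 0.012, 0.0),       # R
    (-0.18, 0.012, 0.030),    # S
    (0.30, 0.060, 0.270),     # T
)
_P_WAVE = (0.15, 0.025, -0.170)


def synthesize_ecg(stream: BeatStream, af_intervals: AFIntervalSet,
                   fs: float = 500.0,
                   seed: int | np.random.Generator = 0,
                   p_free_spans: Optional[list] = None,
                   p_amp_mv: float = 0.15,
                   noise_sd_mv: float = 0.01,
                   fibrillatory_amp_mv: float = 0.05) -> ECGRecord:
    """Template-based lead-II-like trace from beat times.

    A Gaussian P-QRS-T complex is placed at every beat, with P-wave
    amplitude ``p_amp_mv`` (atrial myopathy in the AF-prone phenotype is
    emulated as a reduced amplitude).  Inside AF alarm intervals (and any
    extra ``p_free_spans``, e.g. short atrial runs) the P wave is omitted
    and band-limited fibrillatory baseline noise is added.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration_s = float(stream.times[-1]) + 1.0 if stream.n_beats else 1.0
    n = int(np.ceil(duration_s * fs))
    sig = np.zeros(n)

    p_free = [tuple(x) for x in af_intervals.intervals]
    if p_free_spans:
        p_free.extend(p_free_spans)

    def in_p_free(t: np.ndarray) -> np.ndarray:
        m = np.zeros(t.shape, dtype=bool)
        for s, e in p_free:
            m |= (t >= s) & (t < e)
        return m

    suppress_p = in_p_free(stream.times)
    half = int(0.45 * fs)
    for bt, no_p in zip(stream.times, suppress_p):
        c = int(round(bt * fs))
        lo, hi = max(c - half, 0), min(c + half, n)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs - bt
        p_wave = (p_amp_mv, _P_WAVE[1], _P_WAVE[2])
        waves = _QRST_WAVES if no_p else _QRST_WAVES + (p_wave,)
        for amp, width, off in waves:
            sig[lo:hi] += amp * np.exp(-0.5 * ((tt - off) / width) ** 2)

    if noise_sd_mv > 0:
        sig += rng.normal(0.0, noise_sd_mv, size=n)
    if p_free and fibrillatory_amp_mv > 0:
        # coarse fibrillatory baseline: sum of drifting 4-9 Hz sinusoids
        t_ax = np.arange(n) / fs
        fib = np.zeros(n)
        for f in (4.7, 6.1, 7.9):
            fib += np.sin(2 * np.pi * f * t_ax + rng.uniform(0, 2 * np.pi))
        fib *= fibrillatory_amp_mv / 3.0
        mask = in_p_free(t_ax)
        sig[mask] += fib[mask]
    return ECGRecord(patient_id=stream.patient_id, fs=fs, samples=sig)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _patient_rng(master_seed: int, patient_index: int) -> np.random.Generator:
    """One independent RNG stream per patient, keyed by (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(patient_index)]))


def draw_labels(config: CohortConfig) -> np.ndarray:
    """Per-patient AF labels for a cohort (deterministic in the config seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2 ** 20]))
    u = rng.random(config.n_patients)
    labels = np.full(config.n_patients, LABEL_NO_AF, dtype=object)
    labels[u < config.af_prevalence] = LABEL_NDAF
    thr = config.af_prevalence + config.known_af_fraction
    labels[(u >= config.af_prevalence) & (u < thr)] = LABEL_KNOWN_AF
    return labels


def sample_profile(label: str, effect_sizes: EffectSizes,
                   rng: np.random.Generator) -> dict:
    """Latent HRV/ectopy parameters for one patient.

    Inter-patient heterogeneity is lognormal around group-level means; the
    AF-prone group's short-term-variability amplitudes are multiplied by
    ``rmssd_ratio``, its 1/f slope is lowered by ``2 * dfa_alpha1_shift``
    (for fractional noise the DFA exponent is ~ (beta + 1) / 2), and its
    SVES rate is multiplied by ``sves_rate_ratio``.
    """
    af = label != LABEL_NO_AF
    es = effect_sizes
    st_scale = (es.rmssd_ratio if af else 1.0) * rng.lognormal(0.0, 0.3)
    beta = 1.0 + (2.0 * es.dfa_alpha1_shift if af else 0.0) + rng.normal(0.0, 0.1)
    profile = RRProfile(
        mean_rr_ms=float(np.clip(rng.normal(800.0, 70.0), 550.0, 1100.0)),
        lf_amp=0.03 * rng.lognormal(0.0, 0.25),
        hf_amp=0.02 * st_scale,
        noise_frac=0.025 * st_scale,
        noise_beta=float(np.clip(beta, 0.2, 1.8)),
    )
    sves_rate = 3.0 * (es.sves_rate_ratio if af else 1.0) * rng.lognormal(0.0, 0.7)
    ves_rate = 2.0 * rng.lognormal(0.0, 0.7)
    run_rate = es.short_run_rate if af else 0.05
    # atrial myopathy: AF-prone P waves are lower-amplitude on average
    p_wave_amp = (0.10 if af else 0.15) * rng.lognormal(0.0, 0.1)
    return {
        "p_wave_amp": float(p_wave_amp),
        "profile": profile,
        "sves_rate": float(sves_rate),
        "ves_rate": float(ves_rate),
        "run_rate": float(run_rate),
        "af_episode_rate": 0.3 if label == LABEL_NDAF else (0.6 if label == LABEL_KNOWN_AF else 0.0),
        "o_fraction": 0.01,
    }


def simulate_patient(patient_index: int, label: str, config: CohortConfig,
                     with_ecg: bool = False) -> SyntheticPatient:
    """Generate one synthetic patient (beats, alarms, covariates, ECG)."""
    rng = _patient_rng(config.seed, patient_index)
    params = sample_profile(label, config.effect_sizes, rng)
    stream = simulate_rr_series(params["profile"], config.monitoring_hours, rng)
    pid = f"P{patient_index:04d}"
    stream.patient_id = pid
    # recording start drawn in the morning so day/night windows are defined
    start_hour = float(rng.uniform(8.0, 12.0))
    stream.recording_start = (datetime(2021, 1, 1)
                              + timedelta(seconds=round(start_hour * 3600.0)))

    stream = inject_ectopy(stream, params["sves_rate"], params["ves_rate"], rng)
    stream, run_spans = inject_atrial_runs(stream, params["run_rate"], rng)
    if params["af_episode_rate"] > 0:
        stream, af = inject_af_episodes(stream, params["af_episode_rate"], rng)
    else:
        af = AFIntervalSet.empty()
    stream = relabel_artifacts(stream, params["o_fraction"], rng)

    ecg = None
    if with_ecg:
        ecg = synthesize_ecg(stream, af, fs=config.sampling_rate, seed=rng,
                             p_free_spans=run_spans,
                             p_amp_mv=params["p_wave_amp"])

    stream = insert_monitoring_gaps(stream, config.dropout, rng)
    clinical = sample_clinical_features(label, config.effect_sizes, rng)
    params["run_spans"] = run_spans
    return SyntheticPatient(
        patient_id=pid, label=label, beat_stream=stream, af_intervals=af,
        clinical=clinical, ecg=ecg, ground_truth_params=params,
    )


def simulate_cohort(config: CohortConfig, with_ecg: bool = False) -> list:
    """Generate a full cohort; fully determined by the config (incl. seed)."""
    labels = draw_labels(config)
    return [simulate_patient(i, lab, config, with_ecg=with_ecg)
            for i, lab in enumerate(labels)]


def cohort_manifest(patients: list, config: CohortConfig) -> dict:
    """JSON-serialisable cohort summary."""
    cfg = asdict(config)
    return {
        "config": cfg,
        "n_patients": len(patients),
        "labels": {p.patient_id: p.label for p in patients},
        "n_ndaf": sum(p.label == LABEL_NDAF for p in patients),
        "n_known_af": sum(p.label == LABEL_KNOWN_AF for p in patients),
    }
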