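"""Independent naive reference implementations used only as test oracles.

Everything here is written as directly as possible (explicit loops, full
distance matrices, textbook formulas) and stays independent of the package
code paths it checks.
"""
from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Time-domain HRV
# ---------------------------------------------------------------------------

def naive_time_domain(rr):
    rr = list(map(float, rr))
    n = len(rr)
    mean = sum(rr) / n
    var = sum((x - mean) ** 2 for x in rr) / (n - 1)
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    srt = sorted(rr)
    median = (srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2)
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    return {
        "mean_rr": mean,
        "median_rr": median,
        "sdnn": math.sqrt(var),
        "cvnn": math.sqrt(var) / mean,
        "rmssd": rmssd,
        "pnn50": pnn50,
    }


# ---------------------------------------------------------------------------
# Spectral band power: hand-rolled Welch on the cubic-resampled tachogram
# ---------------------------------------------------------------------------

def naive_welch_band_powers(rr_ms, t_s, fs=4.0, nperseg=256):
    from scipy.interpolate import CubicSpline

    cs = CubicSpline(np.asarray(t_s, float), np.asarray(rr_ms, float))
    grid = np.arange(t_s[0], t_s[-1], 1.0 / fs)
    x = cs(grid)
    nperseg = min(nperseg, x.size)
    step = nperseg // 2
    # periodic Hann window
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    segs = []
    start = 0
    while start + nperseg <= x.size:
        seg = x[start:start + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * win)
        psd = (np.abs(spec) ** 2) / (fs * np.sum(win ** 2))
        psd[1:-1] *= 2.0
        segs.append(psd)
        start += step
    psd = np.mean(segs, axis=0)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)

    def band(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[m], freqs[m]))

    return {"tp": band(0.003, 0.4), "lf": band(0.04, 0.15),
            "hf": band(0.15, 0.4)}


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

def naive_dfa(x, scale_lo, scale_hi):
    x = np.asarray(x, float)
    y = np.cumsum(x - x.mean())
    scales = np.unique(np.round(np.geomspace(scale_lo, scale_hi, 8)).astype(int))
    scales = scales[(scales >= scale_lo) & (scales <= scale_hi) & (scales >= 2)]
    log_n, log_f = [], []
    for n in scales:
        n_boxes = len(y) // n
        if n_boxes < 2:
            continue
        sq = []
        for b in range(n_boxes):
            seg = y[b * n:(b + 1) * n]
            tt = np.arange(n)
            coef = np.polyfit(tt, seg, 1)
            resid = seg - np.polyval(coef, tt)
            sq.extend(resid ** 2)
        f = math.sqrt(np.mean(sq))
        if f > 0:
            log_n.append(math.log(n))
            log_f.append(math.log(f))
    if len(log_n) < 3:
        return float("nan")
    slope = np.polyfit(log_n, log_f, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Sample entropy (full distance-matrix formulation)
# ---------------------------------------------------------------------------

def naive_sampen(x, m=2, r=None):
    x = np.asarray(x, float)
    if r is None:
        r = 0.2 * x.std()

    def matches(mm):
        templ = np.array([x[i:i + mm] for i in range(len(x) - mm + 1)])
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
        iu = np.triu_indices(len(templ), k=1)
        return int(np.sum(d[iu] <= r))

    b = matches(m)
    a = matches(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def naive_mse(x, scales=(1, 2, 3, 4, 5), m=2):
    x = np.asarray(x, float)
    r = 0.2 * x.std()
    vals = []
    for s in scales:
        n = len(x) // s
        if n <= m + 1:
            continue
        cg = np.array([x[i * s:(i + 1) * s].mean() for i in range(n)])
        v = naive_sampen(cg, m=m, r=r)
        if np.isfinite(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# ROC-AUC by brute-force pairwise concordance
# ---------------------------------------------------------------------------

def brute_force_auc(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
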