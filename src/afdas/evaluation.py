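"""Evaluation protocol: ROC-AUC, bootstrap CIs, DeLong/Fisher, thresholds.

Discrimination is summarised by the ROC-AUC in its rank (Mann-Whitney)
formulation with ties counted one half.  Confidence intervals come from
stratified patient-level percentile bootstrap (200 resamples per fold on
derivation data, 1000 on validation runs).  Paired model comparisons use
the DeLong structural-component test per fold, aggregated across folds with
Fisher's method.  For clinical reporting a decision threshold is fixed once
on derivation scores at 90% specificity and then frozen; sensitivity,
specificity, PPV and NPV are read off the resulting 2x2 table.  Secondary-
metric comparisons use paired t-tests over bootstrap resamples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# ROC-AUC
# ---------------------------------------------------------------------------

def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    pos = y == 1
    neg = y == 0
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def bootstrap_auc_ci(labels: np.ndarray, scores: np.ndarray,
                     n_boot: int = 1000, seed: int = 0,
                     level: float = 0.95) -> Tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = roc_auc(y[idx], s[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, s: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC and the structural components V10 (positives), V01 (negatives)."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def delong_test(labels: np.ndarray, scores_a: np.ndarray,
                scores_b: np.ndarray) -> float:
    """Two-sided p-value for H0: AUC_a = AUC_b on paired scores.

    Uses the DeLong covariance of the paired structural components.  If the
    variance of the difference vanishes (identical AUC structure, e.g. a
    monotone transform of the same scores), p = 1 by convention.
    """
    y = np.asarray(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("paired inputs must share one set of patients")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _delong_components(y, a)
    auc_b, v10_b, v01_b = _delong_components(y, b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square(2k)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    if (p == 0).any():
        warnings.warn("p-value of 0 clipped to machine minimum before "
                      "Fisher combination", RuntimeWarning)
    p = np.clip(p, tiny, 1.0)
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, df=2 * p.size))


# ---------------------------------------------------------------------------
# Threshold selection and confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSpec:
    """Decision threshold frozen on derivation data."""

    threshold: float
    target_specificity: float
    achieved_specificity: float
    achieved_sensitivity: float


def threshold_at_specificity(labels: np.ndarray, scores: np.ndarray,
                             target: float = 0.90) -> ThresholdSpec:
    """Smallest threshold whose derivation specificity meets the target.

    Predicted-positive means ``score >= threshold``; among thresholds with
    specificity >= target the smallest (maximum-sensitivity) one is chosen.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    neg = s[y == 0]
    if neg.size == 0:
        raise ValueError("negatives required to anchor specificity")
    candidates = np.unique(s)
    if candidates.size < 2:
        raise ValueError("target specificity unattainable: all scores equal")
    candidates = np.concatenate([candidates, [np.nextafter(s.max(), np.inf)]])
    for thr in candidates:
        spec = float(np.mean(neg < thr))
        if spec >= target:
            sens = float(np.mean(s[y == 1] >= thr)) if (y == 1).any() else float("nan")
            return ThresholdSpec(threshold=float(thr), target_specificity=target,
                                 achieved_specificity=spec,
                                 achieved_sensitivity=sens)
    raise ValueError("target specificity unattainable (all scores equal?)")


def confusion_metrics(labels: np.ndarray, scores: np.ndarray,
                      threshold: float) -> Dict[str, Optional[float]]:
    """Sens/spec/PPV/NPV at a threshold; 0/0 ratios reported as None."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    y = np.asarray(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def ratio(a: int, b: int) -> Optional[float]:
        return a / b if b > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


# ---------------------------------------------------------------------------
# Paired bootstrap test on secondary metrics
# ---------------------------------------------------------------------------

def paired_bootstrap_metric_test(labels: np.ndarray,
                                 scores_a: np.ndarray, scores_b: np.ndarray,
                                 metric: str,
                                 threshold_a: float, threshold_b: float,
                                 n_boot: int = 1000, seed: int = 0,
                                 max_undefined_frac: float = 0.10) -> float:
    """Paired t-test over bootstrap resamples of a thresholded metric.

    Each stratified resample is scored with both models at their own frozen
    thresholds; the two-sided p-value comes from a one-sample t-test of the
    per-resample differences against zero.
    """
    y = np.asarray(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("paired inputs must share one set of patients")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    diffs = []
    n_undefined = 0
    for _ in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        ma = confusion_metrics(y[idx], a[idx], threshold_a)[metric]
        mb = confusion_metrics(y[idx], b[idx], threshold_b)[metric]
        if ma is None or mb is None:
            n_undefined += 1
            continue
        diffs.append(ma - mb)
    if n_undefined > max_undefined_frac * n_boot:
        raise ValueError(
            f"metric {metric!r} undefined in {n_undefined}/{n_boot} resamples")
    diffs = np.asarray(diffs)
    if np.allclose(diffs, diffs[0]):
        return 1.0 if abs(diffs[0]) < 1e-12 else 0.0
    t = stats.ttest_1samp(diffs, 0.0)
    return float(t.pvalue)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Summary of one evaluation run."""

    auc: float
    ci: Tuple[float, float]
    per_fold_aucs: List[float] = field(default_factory=list)
    threshold: Optional[ThresholdSpec] = None
    metrics_at_threshold: Optional[dict] = None
    comparisons: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "ci": list(self.ci),
            "per_fold_aucs": self.per_fold_aucs,
            "comparisons": self.comparisons,
        }
        if self.threshold is not None:
            d["threshold"] = {
                "value": self.threshold.threshold,
                "target_specificity": self.threshold.target_specificity,
                "achieved_specificity": self.threshold.achieved_specificity,
                "achieved_sensitivity": self.threshold.achieved_sensitivity,
            }
        if self.metrics_at_threshold is not None:
            d["metrics_at_threshold"] = self.metrics_at_threshold
        return d


def evaluate_predictions(labels: Dict[str, int], preds: Dict[str, float],
                         n_boot: int = 1000, seed: int = 0,
                         threshold: Optional[ThresholdSpec] = None) -> EvaluationReport:
    """Single-run evaluation of one prediction set (validation style)."""
    ids = sorted(set(labels) & set(preds))
    y = np.array([labels[i] for i in ids])
    s = np.array([preds[i] for i in ids])
    auc = roc_auc(y, s)
    ci = bootstrap_auc_ci(y, s, n_boot=n_boot, seed=seed)
    metrics = None
    if threshold is not None:
        metrics = confusion_metrics(y, s, threshold.threshold)
    return EvaluationReport(auc=auc, ci=ci, threshold=threshold,
                            metrics_at_threshold=metrics)


def compare_models_foldwise(labels: Dict[str, int],
                            folds_a: List[Dict[str, float]],
                            folds_b: List[Dict[str, float]]) -> float:
    """Per-fold DeLong on shared test sets, aggregated by Fisher's method."""
    if len(folds_a) != len(folds_b):
        raise ValueError("models must be evaluated on the same fold plan")
    ps = []
    for pa, pb in zip(folds_a, folds_b):
        ids = sorted(set(pa) & set(pb))
        if not ids:
            raise ValueError("fold test sets do not overlap")
        y = np.array([labels[i] for i in ids])
        if np.unique(y).size < 2:
            continue
        a = np.array([pa[i] for i in ids])
        b = np.array([pb[i] for i in ids])
        ps.append(delong_test(y, a, b))
    if not ps:
        raise ValueError("no fold allowed a paired comparison")
    return fisher_combine(ps)
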