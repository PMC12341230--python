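"""Bayesian fusion of classifier probabilities and the AS5F benchmark.

Two models' per-patient AF probabilities are combined by the independent-
odds product (Bayesian model averaging with a flat prior):

    P = p1 * p2 / (p1 * p2 + (1 - p1) * (1 - p2))

which in log-odds form is simply ``logit(P) = logit(p1) + logit(p2)``.
The pair (0, 1) is singular (0/0), so inputs are clipped away from the
endpoints before evaluation.

The AS5F comparator is a published clinical risk score using only age and
admission NIHSS.  Its coefficients are *injected configuration* — this
package does not hard-code the published nomogram; callers must supply
coefficients (see :func:`synthetic_as5f_coefficients` for a clearly marked
synthetic stand-in used in simulation benchmarks).
"""
from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np

DEFAULT_EPS = 1e-6


def bayes_fuse(p1, p2, eps: float = DEFAULT_EPS):
    """Fuse two probabilities by the independent-odds product.

    Symmetric in its arguments; 0.5 is the identity element.  Accepts
    scalars or arrays.  Inputs are clipped to ``[eps, 1 - eps]``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
        raise ValueError("probabilities must be finite")
    if (p1 < 0).any() or (p1 > 1).any() or (p2 < 0).any() or (p2 > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    a = np.clip(p1, eps, 1.0 - eps)
    b = np.clip(p2, eps, 1.0 - eps)
    num = a * b
    out = num / (num + (1.0 - a) * (1.0 - b))
    return float(out) if out.ndim == 0 else out


def fuse_prediction_sets(preds_a: Dict[str, float], preds_b: Dict[str, float],
                         eps: float = DEFAULT_EPS) -> Dict[str, float]:
    """Patient-wise fusion over the intersection of two prediction sets."""
    common = sorted(set(preds_a) & set(preds_b))
    return {pid: bayes_fuse(preds_a[pid], preds_b[pid], eps=eps)
            for pid in common}


# ---------------------------------------------------------------------------
# AS5F benchmark
# ---------------------------------------------------------------------------

def as5f_score(age: float, nihss: int,
               coefficients: Optional[Mapping[str, float]]) -> float:
    """Age/NIHSS ranking score with pluggable coefficients.

    ``coefficients`` must contain ``age`` and ``nihss`` weights (and an
    optional ``intercept``), both non-negative so the score is monotone
    non-decreasing in each input, as required of a ranking comparator.
    """
    if coefficients is None:
        raise ValueError(
            "AS5F coefficients are not bundled; supply them from the score's "
            "source publication via configuration")
    if age <= 0:
        raise ValueError("age must be positive")
    if not 0 <= nihss <= 42:
        raise ValueError("NIHSS must lie in [0, 42]")
    for key in ("age", "nihss"):
        if key not in coefficients:
            raise ValueError(f"missing AS5F coefficient {key!r}")
        if coefficients[key] < 0:
            raise ValueError("AS5F coefficients must be non-negative "
                             "(score is monotone in age and NIHSS)")
    return float(coefficients.get("intercept", 0.0)
                 + coefficients["age"] * age
                 + coefficients["nihss"] * nihss)


def synthetic_as5f_coefficients() -> Dict[str, float]:
    """SYNTHETIC stand-in coefficients for simulation benchmarks.

    These are *not* the published AS5F weights; they only provide a
    monotone age/NIHSS ranking score so that benchmark plumbing can be
    exercised on synthetic cohorts.
    """
    return {"age": 1.0, "nihss": 2.5, "intercept": 0.0}


def as5f_prediction_set(clinical: "Mapping[str, Mapping[str, float]] | object",
                        coefficients: Optional[Mapping[str, float]]) -> Dict[str, float]:
    """AS5F scores for a clinical table (DataFrame with age/nihss columns
    indexed by patient id, or a mapping of patient id -> record)."""
    import pandas as pd

    if isinstance(clinical, pd.DataFrame):
        return {pid: as5f_score(row["age"], int(row["nihss"]), coefficients)
                for pid, row in clinical.iterrows()}
    return {pid: as5f_score(rec["age"], int(rec["nihss"]), coefficients)
            for pid, rec in clinical.items()}
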