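"""Classifier training under patient-level nested cross-validation.

Outer loop: stratified shuffle-split on patient identifiers (5 splits, 20%
test size, shared seed so every model kind is evaluated on identical test
sets and fold-wise paired ROC comparisons are well defined).  Inner loop:
randomised search over a fixed candidate family (gradient boosting, random
forest, regularised logistic regression) scored by 3-fold stratified inner
ROC-AUC; median imputation (and scaling, for the linear family) are fitted
on the training fold only.

The raw-ECG branch is a small 1-D convolutional network implemented in
numpy (conv -> ReLU -> mean+max pooling -> logistic head) trained with Adam
(learning rate 0.001) for 20 epochs under binary cross-entropy; per-patient
risk is the mean probability over k randomly chosen 5.12-s segments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .evaluation import roc_auc

MODEL_KINDS = (
    "ensemble_clinical", "ensemble_hrv", "ensemble_hrv_clinical",
    "ensemble_age_hrv_final", "cnn_raw_ecg",
)


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Patient-level stratified shuffle-split folds, reused across models."""

    folds: List[Tuple[np.ndarray, np.ndarray]]  # (train_ids, test_ids)
    test_fraction: float
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.folds)


def make_patient_splits(labels: Dict[str, int], n_splits: int = 5,
                        test_frac: float = 0.2, seed: int = 0) -> SplitPlan:
    """Stratified shuffle splits over patient ids.

    The returned plan is the single source of folds for every model kind in
    a comparison run, so per-fold DeLong comparisons share test sets.
    """
    ids = np.array(sorted(labels))
    y = np.array([labels[i] for i in ids])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 patients in each class")
    sss = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_frac,
                                 random_state=seed)
    folds = [(ids[tr], ids[te]) for tr, te in sss.split(ids, y)]
    return SplitPlan(folds=folds, test_fraction=test_frac, seed=seed)


# ---------------------------------------------------------------------------
# Randomised-search ensemble
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    kind: str
    pipeline: Pipeline
    schema: Tuple[str, ...]
    search_log: List[dict] = field(default_factory=list)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.schema if c not in X.columns]
        if missing:
            raise ValueError(f"feature schema mismatch, missing columns: {missing}")
        return self.pipeline.predict_proba(X[list(self.schema)])[:, 1]


def _draw_candidate(rng: np.random.Generator, seed: int) -> Tuple[str, Pipeline, dict]:
    """One random (family, pipeline) draw from the documented search space."""
    family = rng.choice(["gbc", "rf", "logreg"])
    if family == "gbc":
        params = {
            "n_estimators": int(rng.choice([50, 100, 200])),
            "learning_rate": float(rng.choice([0.03, 0.1, 0.3])),
            "max_depth": int(rng.choice([2, 3])),
            "subsample": float(rng.choice([0.7, 1.0])),
        }
        est = GradientBoostingClassifier(random_state=seed, **params)
        steps = [("impute", SimpleImputer(strategy="median")), ("model", est)]
    elif family == "rf":
        depth = int(rng.choice([0, 3, 5]))
        params = {
            "n_estimators": int(rng.choice([100, 300])),
            "max_depth": depth if depth > 0 else None,
            "min_samples_leaf": int(rng.choice([1, 3, 5])),
        }
        est = RandomForestClassifier(random_state=seed, class_weight="balanced",
                                     n_jobs=1, **params)
        steps = [("impute", SimpleImputer(strategy="median")), ("model", est)]
    else:
        params = {"C": float(10.0 ** rng.uniform(-2, 2))}
        est = LogisticRegression(max_iter=2000, class_weight="balanced", **params)
        steps = [("impute", SimpleImputer(strategy="median")),
                 ("scale", StandardScaler()), ("model", est)]
    return str(family), Pipeline(steps), params


def train_ensemble(features: pd.DataFrame, labels: Dict[str, int],
                   kind: str = "ensemble_age_hrv_final",
                   search_budget: int = 10, inner_k: int = 3,
                   seed: int = 0) -> TrainedModel:
    """Fit the randomised-search ensemble on one training fold.

    ``features`` rows are indexed by patient id; only ids present in
    ``labels`` are used (leakage guard: callers pass the training fold
    only).  Selection is by mean inner stratified-CV ROC-AUC.
    """
    ids = [i for i in features.index if i in labels]
    X = features.loc[ids]
    y = np.array([labels[i] for i in ids])
    if np.unique(y).size < 2:
        raise ValueError("training fold contains a single class")
    rng = np.random.default_rng(seed)
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    best = None
    log = []
    for j in range(search_budget):
        family, pipe, params = _draw_candidate(rng, seed)
        aucs = []
        for tr, te in inner.split(X, y):
            if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                continue
            pipe.fit(X.iloc[tr], y[tr])
            p = pipe.predict_proba(X.iloc[te])[:, 1]
            aucs.append(roc_auc(y[te], p))
        score = float(np.mean(aucs)) if aucs else float("nan")
        log.append({"draw": j, "family": family, "params": params,
                    "inner_auc": score})
        if np.isfinite(score) and (best is None or score > best[0]):
            best = (score, family, params)
    if best is None:
        raise RuntimeError("inner CV produced no valid candidate")
    # refit the winning candidate on the full training fold
    rng2 = np.random.default_rng(seed)
    refit = None
    for j in range(search_budget):
        family, pipe, params = _draw_candidate(rng2, seed)
        if family == best[1] and params == best[2]:
            refit = pipe
    assert refit is not None
    refit.fit(X, y)
    return TrainedModel(kind=kind, pipeline=refit,
                        schema=tuple(X.columns), search_log=log)


def predict(model: TrainedModel, features: pd.DataFrame) -> Dict[str, float]:
    """Per-patient AF probability (PredictionSet)."""
    if features.shape[0] == 0:
        return {}
    p = model.predict_proba(features)
    return {pid: float(pi) for pid, pi in zip(features.index, p)}


def run_nested_cv(features: pd.DataFrame, labels: Dict[str, int],
                  plan: SplitPlan, kind: str = "ensemble_age_hrv_final",
                  search_budget: int = 10, inner_k: int = 3,
                  seed: int = 0) -> dict:
    """Outer-fold predictions and ROC-AUCs under a shared split plan."""
    fold_predictions: List[Dict[str, float]] = []
    fold_aucs: List[float] = []
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        tr_labels = {i: labels[i] for i in train_ids if i in features.index}
        model = train_ensemble(features, tr_labels, kind=kind,
                               search_budget=search_budget,
                               inner_k=inner_k, seed=seed + f)
        test_ids_av = [i for i in test_ids if i in features.index]
        preds = predict(model, features.loc[test_ids_av])
        y_te = np.array([labels[i] for i in test_ids_av])
        p_te = np.array([preds[i] for i in test_ids_av])
        fold_predictions.append(preds)
        fold_aucs.append(roc_auc(y_te, p_te) if np.unique(y_te).size > 1
                         else float("nan"))
    return {
        "fold_predictions": fold_predictions,
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.nanmean(fold_aucs)),
    }


# ---------------------------------------------------------------------------
# 1-D CNN for raw 5.12-s ECG segments (numpy implementation)
# ---------------------------------------------------------------------------

class Conv1dNet:
    """Small 1-D convolutional classifier for fixed-length ECG windows.

    One convolutional layer (``n_filters`` kernels of ``kernel`` samples,
    stride ``stride``) with ReLU, global mean+max pooling, and a logistic
    output head.  Trained with Adam on binary cross-entropy.  Single
    threaded and fully deterministic given the seed.
    """

    def __init__(self, input_len: int = 2560, n_filters: int = 16,
                 kernel: int = 128, stride: int = 16, seed: int = 0):
        self.input_len = input_len
        self.n_filters = n_filters
        self.kernel = kernel
        self.stride = stride
        self.seed = seed
        rng = np.random.default_rng(seed)
        scale = np.sqrt(2.0 / kernel)
        self.W = rng.normal(0.0, scale, size=(n_filters, kernel))
        self.bc = np.zeros(n_filters)
        self.w_out = rng.normal(0.0, 0.1, size=2 * n_filters)
        self.b_out = 0.0
        self.history: List[float] = []

    # -- forward pieces ----------------------------------------------------
    def _frames(self, X: np.ndarray) -> np.ndarray:
        n_pos = (X.shape[1] - self.kernel) // self.stride + 1
        idx = (np.arange(n_pos)[:, None] * self.stride
               + np.arange(self.kernel)[None, :])
        return X[:, idx]  # (N, n_pos, kernel)

    @staticmethod
    def _standardize(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        return (X - mu) / np.where(sd > 0, sd, 1.0)

    def _forward(self, X: np.ndarray):
        frames = self._frames(self._standardize(X))
        conv = frames @ self.W.T + self.bc          # (N, L, F)
        act = np.maximum(conv, 0.0)
        mean_pool = act.mean(axis=1)                # (N, F)
        argmax = act.argmax(axis=1)                 # (N, F)
        max_pool = np.take_along_axis(act, argmax[:, None, :], axis=1)[:, 0, :]
        feats = np.concatenate([mean_pool, max_pool], axis=1)
        logits = feats @ self.w_out + self.b_out
        p = 1.0 / (1.0 + np.exp(-logits))
        cache = (frames, conv, act, argmax, feats)
        return p, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for lo in range(0, X.shape[0], 512):
            out[lo:lo + 512] = self._forward(X[lo:lo + 512])[0]
        return out

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 20,
            lr: float = 0.001, batch_size: int = 64) -> "Conv1dNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed + 1)
        params = [self.W, self.bc, self.w_out]
        m = [np.zeros_like(p) for p in params] + [0.0]
        v = [np.zeros_like(p) for p in params] + [0.0]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(X.shape[0])
            losses = []
            for lo in range(0, X.shape[0], batch_size):
                idx = order[lo:lo + batch_size]
                xb, yb = X[idx], y[idx]
                p, (frames, conv, act, argmax, feats) = self._forward(xb)
                pc = np.clip(p, 1e-12, 1 - 1e-12)
                losses.append(float(-np.mean(yb * np.log(pc)
                                             + (1 - yb) * np.log(1 - pc))))
                n = xb.shape[0]
                dlogit = (p - yb) / n                       # (N,)
                g_wout = feats.T @ dlogit
                g_bout = float(dlogit.sum())
                dfeats = np.outer(dlogit, self.w_out)       # (N, 2F)
                F = self.n_filters
                L = act.shape[1]
                dact = np.zeros_like(act)
                dact += dfeats[:, None, :F] / L             # mean-pool path
                np.put_along_axis(
                    dact, argmax[:, None, :],
                    np.take_along_axis(dact, argmax[:, None, :], axis=1)
                    + dfeats[:, None, F:], axis=1)
                dconv = dact * (conv > 0)
                g_W = np.einsum("nlf,nlk->fk", dconv, frames)
                g_bc = dconv.sum(axis=(0, 1))
                grads = [g_W, g_bc, g_wout, g_bout]
                step += 1
                for k in range(4):
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * (grads[k] * grads[k]
                                                   if k < 3 else grads[k] ** 2)
                    mhat = m[k] / (1 - b1 ** step)
                    vhat = v[k] / (1 - b2 ** step)
                    upd = lr * mhat / (np.sqrt(vhat) + eps)
                    if k == 0:
                        self.W -= upd
                    elif k == 1:
                        self.bc -= upd
                    elif k == 2:
                        self.w_out -= upd
                    else:
                        self.b_out -= upd
            self.history.append(float(np.mean(losses)))
        return self


@dataclass
class SegmentDataset:
    """Per-patient stacks of fixed-length ECG segments with patient labels."""

    segments: Dict[str, np.ndarray]   # patient_id -> (n_seg, 2560)
    labels: Dict[str, int]

    def stacked(self, ids: Sequence[str]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs, ys, pids = [], [], []
        for pid in ids:
            seg = self.segments.get(pid)
            if seg is None or seg.shape[0] == 0:
                continue
            xs.append(seg)
            ys.append(np.full(seg.shape[0], self.labels[pid]))
            pids.append(np.full(seg.shape[0], pid, dtype=object))
        if not xs:
            return (np.empty((0, 0)), np.empty(0), np.empty(0, dtype=object))
        return np.vstack(xs), np.concatenate(ys), np.concatenate(pids)


def train_cnn(dataset: SegmentDataset, train_ids: Sequence[str],
              epochs: int = 20, lr: float = 0.001, seed: int = 0,
              min_segments_per_class: int = 10, **net_kwargs) -> Conv1dNet:
    """Train the 1-D CNN on the training patients' segments."""
    X, y, _ = dataset.stacked(train_ids)
    if X.shape[0] == 0:
        raise ValueError("no training segments")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < min_segments_per_class:
        raise ValueError(
            f"need >= {min_segments_per_class} segments per class, "
            f"got pos={n_pos}, neg={n_neg}")
    net = Conv1dNet(input_len=X.shape[1], seed=seed, **net_kwargs)
    net.fit(X, y, epochs=epochs, lr=lr)
    return net


def segment_predictions(net: Conv1dNet, dataset: SegmentDataset,
                        ids: Sequence[str]) -> Dict[str, np.ndarray]:
    """Per-patient arrays of per-segment probabilities."""
    out = {}
    for pid in ids:
        seg = dataset.segments.get(pid)
        if seg is None or seg.shape[0] == 0:
            continue
        out[pid] = net.predict_proba(seg)
    return out


def aggregate_segment_predictions(per_segment: Dict[str, np.ndarray], k: int,
                                  seed: int | np.random.Generator = 0) -> Dict[str, float]:
    """Mean probability over k randomly chosen segments per patient."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = {}
    for pid in sorted(per_segment):
        probs = per_segment[pid]
        if probs.size == 0:
            continue
        kk = min(k, probs.size)
        idx = rng.choice(probs.size, size=kk, replace=False)
        out[pid] = float(np.mean(probs[idx]))
    return out


# ---------------------------------------------------------------------------
# Feature attribution
# ---------------------------------------------------------------------------

def feature_attribution(model: TrainedModel, features: pd.DataFrame,
                        labels: Dict[str, int], n_repeats: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Permutation importance with a sign from feature-risk rank correlation.

    Importance is the mean drop in ROC-AUC when a column is shuffled;
    the sign indicates the direction of the feature's marginal association
    with predicted risk.  Returned sorted by |importance| descending.
    """
    ids = [i for i in features.index if i in labels]
    X = features.loc[ids, list(model.schema)]
    y = np.array([labels[i] for i in ids])
    rng = np.random.default_rng(seed)
    base_p = model.predict_proba(X)
    base_auc = roc_auc(y, base_p)
    rows = []
    for col in model.schema:
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].values)
            drops.append(base_auc - roc_auc(y, model.predict_proba(Xp)))
        x = X[col].values
        if np.unique(x[~pd.isna(x)]).size > 1:
            rho = spearmanr(x, base_p, nan_policy="omit").statistic
            sgn = 1.0 if (np.isnan(rho) or rho >= 0) else -1.0
        else:
            sgn = 1.0
        rows.append({"feature": col,
                     "importance": float(np.mean(drops)),
                     "signed_importance": sgn * abs(float(np.mean(drops)))})
    df = pd.DataFrame(rows).set_index("feature")
    return df.reindex(df["importance"].abs().sort_values(ascending=False).index)


def fold_averaged_attribution(features: pd.DataFrame, labels: Dict[str, int],
                              plan: SplitPlan, kind: str = "ensemble_hrv_clinical",
                              search_budget: int = 6, seed: int = 0) -> pd.DataFrame:
    """Attribution averaged across cross-validation folds."""
    acc = None
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        tr = {i: labels[i] for i in train_ids if i in features.index}
        model = train_ensemble(features, tr, kind=kind,
                               search_budget=search_budget, seed=seed + f)
        te = {i: labels[i] for i in test_ids if i in features.index}
        att = feature_attribution(model, features.loc[list(te)], te, seed=seed + f)
        acc = att if acc is None else acc.add(att, fill_value=0.0)
    acc = acc / plan.n_splits
    return acc.reindex(acc["importance"].abs().sort_values(ascending=False).index)
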