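"""End-to-end study harness: cohort -> features -> models -> evaluation.

These helpers wire the modules together the way the derivation-validation
study runs: simulate (or load) a cohort, clean each patient's beat stream,
compute first-hour HRV features plus age, train the ensemble under the
shared patient-level split plan, and report fold AUCs, a 90%-specificity
threshold frozen on derivation data, and its transfer to a fresh cohort.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import hrv, preprocessing
from .evaluation import (bootstrap_auc_ci, confusion_metrics, roc_auc,
                         threshold_at_specificity)
from .modeling import (make_patient_splits, predict, run_nested_cv,
                       train_ensemble)
from .synthetic import (LABEL_KNOWN_AF, LABEL_NDAF, CohortConfig,
                        SyntheticPatient, simulate_cohort)

FINAL_MODEL_HOURS = 1.0


def binary_labels(patients: List[SyntheticPatient],
                  include_known_af: bool = False) -> Dict[str, int]:
    """AF label map; pre-known AF excluded from the primary analysis."""
    out = {}
    for p in patients:
        if p.label == LABEL_KNOWN_AF and not include_known_af:
            continue
        out[p.patient_id] = int(p.label in (LABEL_NDAF, LABEL_KNOWN_AF))
    return out


def cohort_features(patients: List[SyntheticPatient],
                    first_hours: Optional[float] = FINAL_MODEL_HOURS,
                    include_age: bool = True,
                    buffer_s: float = preprocessing.AF_BUFFER_S) -> pd.DataFrame:
    """HRV feature matrix (optionally + age) from raw cohort data.

    Runs the full cleaning chain per patient (AF excision with buffer,
    label filtering, gap interpolation, 5-min tiling) before featurising.
    Patients with no usable segment are dropped.
    """
    rows = []
    ages = {}
    for p in patients:
        segments = preprocessing.preprocess_stream(
            p.beat_stream, p.af_intervals, buffer_s=buffer_s)
        row = hrv.featurize_patient(segments, first_hours=first_hours)
        if row is None:
            continue
        rows.append(row)
        ages[p.patient_id] = p.clinical.age
    df = hrv.feature_matrix(rows)
    if include_age:
        df["age"] = pd.Series(ages)
    return df


def clinical_features(patients: List[SyntheticPatient]) -> pd.DataFrame:
    rows = [{"patient_id": p.patient_id, **p.clinical.as_dict()}
            for p in patients]
    return pd.DataFrame(rows).set_index("patient_id")


def run_final_model_cv(config: CohortConfig, seed: int = 0,
                       search_budget: int = 8,
                       first_hours: float = FINAL_MODEL_HOURS,
                       patients: Optional[List[SyntheticPatient]] = None) -> dict:
    """Derivation-style nested CV of the age + first-hour-HRV model."""
    if patients is None:
        patients = simulate_cohort(config)
    labels = binary_labels(patients)
    feats = cohort_features(patients, first_hours=first_hours)
    feats = feats.loc[[i for i in feats.index if i in labels]]
    plan = make_patient_splits(
        {i: labels[i] for i in feats.index}, n_splits=5, test_frac=0.2,
        seed=seed)
    result = run_nested_cv(feats, labels, plan,
                           kind="ensemble_age_hrv_final",
                           search_budget=search_budget, seed=seed)
    result.update({"features": feats, "labels": labels, "plan": plan,
                   "patients": patients})
    return result


def pooled_oof_scores(result: dict) -> Tuple[np.ndarray, np.ndarray]:
    """Pool out-of-fold predictions (a patient may appear in several folds;
    its scores are averaged)."""
    labels = result["labels"]
    acc: Dict[str, list] = {}
    for fold in result["fold_predictions"]:
        for pid, p in fold.items():
            acc.setdefault(pid, []).append(p)
    ids = sorted(acc)
    y = np.array([labels[i] for i in ids])
    s = np.array([float(np.mean(acc[i])) for i in ids])
    return y, s


def derive_and_validate(derivation_cfg: CohortConfig,
                        validation_cfg: CohortConfig,
                        seed: int = 0, search_budget: int = 8,
                        target_specificity: float = 0.90,
                        n_boot: int = 1000) -> dict:
    """Full protocol: CV on derivation, frozen threshold, fresh validation.

    The decision threshold is fixed on pooled out-of-fold derivation scores
    at the target specificity, then applied unchanged to a freshly
    simulated validation cohort scored by a model refit on the entire
    derivation cohort.
    """
    deriv = run_final_model_cv(derivation_cfg, seed=seed,
                               search_budget=search_budget)
    y_d, s_d = pooled_oof_scores(deriv)
    thr = threshold_at_specificity(y_d, s_d, target=target_specificity)

    final_model = train_ensemble(deriv["features"], deriv["labels"],
                                 kind="ensemble_age_hrv_final",
                                 search_budget=search_budget, seed=seed)

    val_patients = simulate_cohort(validation_cfg)
    val_labels = binary_labels(val_patients)
    val_feats = cohort_features(val_patients)
    val_feats = val_feats.loc[[i for i in val_feats.index if i in val_labels]]
    val_preds = predict(final_model, val_feats)
    ids = sorted(val_preds)
    y_v = np.array([val_labels[i] for i in ids])
    s_v = np.array([val_preds[i] for i in ids])
    return {
        "derivation": deriv,
        "threshold": thr,
        "final_model": final_model,
        "validation_labels": val_labels,
        "validation_predictions": val_preds,
        "validation_auc": roc_auc(y_v, s_v),
        "validation_ci": bootstrap_auc_ci(y_v, s_v, n_boot=n_boot, seed=seed),
        "validation_metrics": confusion_metrics(y_v, s_v, thr.threshold),
    }


def permuted_label_aucs(features: pd.DataFrame, labels: Dict[str, int],
                        n_seeds: int = 50, search_budget: int = 2,
                        seed: int = 0) -> np.ndarray:
    """Null calibration: nested-CV mean AUC under label permutation.

    Features are held fixed; labels are randomly permuted across patients
    for each replicate, breaking any feature-outcome association.
    """
    ids = sorted(i for i in features.index if i in labels)
    y = np.array([labels[i] for i in ids])
    aucs = np.empty(n_seeds)
    for r in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 + r)
        y_perm = rng.permutation(y)
        perm_labels = {i: int(v) for i, v in zip(ids, y_perm)}
        plan = make_patient_splits(perm_labels, seed=seed + r)
        res = run_nested_cv(features.loc[ids], perm_labels, plan,
                            search_budget=search_budget, seed=seed + r)
        aucs[r] = res["mean_auc"]
    return aucs
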