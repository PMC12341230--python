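"""Plain-text I/O: beat CSVs, alarm CSVs, clinical tables, cohort manifests.

Formats
-------
beat CSV     : columns ``time_s,label`` (one file per patient)
alarm CSV    : columns ``start_s,end_s`` (half-open seconds)
clinical CSV : one row per patient, columns = patient_id + covariates + label
ECG CSV      : single column ``mv`` with a ``# fs=<Hz>`` header comment
manifest     : JSON with the generating configuration and label map
"""
from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .datatypes import AFIntervalSet, BeatStream, ECGRecord
from .synthetic import CohortConfig, SyntheticPatient, cohort_manifest

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def write_beats_csv(stream: BeatStream, path: Path) -> None:
    df = pd.DataFrame({"time_s": stream.times, "label": stream.labels})
    with open(path, "w") as fh:
        fh.write(f"# recording_start={stream.recording_start.strftime(_TIME_FMT)}\n")
        df.to_csv(fh, index=False)


def read_beats_csv(path: Path, patient_id: str = "") -> BeatStream:
    with open(path) as fh:
        first = fh.readline()
        start = datetime(2021, 1, 1)
        if first.startswith("# recording_start="):
            start = datetime.strptime(first.split("=", 1)[1].strip(), _TIME_FMT)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return BeatStream(
        patient_id=patient_id or Path(path).stem,
        times=df["time_s"].to_numpy(float),
        labels=df["label"].to_numpy(str),
        recording_start=start,
    )


def write_alarms_csv(af: AFIntervalSet, path: Path) -> None:
    pd.DataFrame(af.intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_alarms_csv(path: Path) -> AFIntervalSet:
    df = pd.read_csv(path)
    if df.empty:
        return AFIntervalSet.empty()
    return AFIntervalSet(df[["start_s", "end_s"]].to_numpy(float))


def write_ecg_csv(record: ECGRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs}\nmv\n")
        np.savetxt(fh, record.samples, fmt="%.5f")


def read_ecg_csv(path: Path, patient_id: str = "") -> ECGRecord:
    with open(path) as fh:
        header = fh.readline()
        fs = float(header.split("=", 1)[1]) if "fs=" in header else 500.0
        fh.readline()  # column name
        samples = np.loadtxt(fh)
    return ECGRecord(patient_id=patient_id or Path(path).stem, fs=fs, samples=samples)


def clinical_table(patients: List[SyntheticPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        rows.append({"patient_id": p.patient_id, **p.clinical.as_dict(),
                     "label": p.label})
    return pd.DataFrame(rows).set_index("patient_id")


def write_cohort(patients: List[SyntheticPatient], config: CohortConfig,
                 out_dir: Path, with_ecg: bool = False) -> None:
    """Serialise a cohort: per-patient beat/alarm CSVs, clinical CSV, manifest."""
    out = Path(out_dir)
    (out / "beats").mkdir(parents=True, exist_ok=True)
    (out / "alarms").mkdir(exist_ok=True)
    if with_ecg:
        (out / "ecg").mkdir(exist_ok=True)
    for p in patients:
        write_beats_csv(p.beat_stream, out / "beats" / f"{p.patient_id}.csv")
        write_alarms_csv(p.af_intervals, out / "alarms" / f"{p.patient_id}.csv")
        if with_ecg and p.ecg is not None:
            write_ecg_csv(p.ecg, out / "ecg" / f"{p.patient_id}.csv")
    clinical_table(patients).to_csv(out / "clinical.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort_manifest(patients, config), fh, indent=2)


def write_feature_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path)


def read_feature_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
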