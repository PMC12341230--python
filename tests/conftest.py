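import numpy as np
import pytest

from afdas.pipeline import binary_labels, cohort_features
from afdas.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Short-monitoring cohort with a high AF fraction for group-contrast tests."""
    cfg = CohortConfig(n_patients=60, af_prevalence=0.3,
                       monitoring_hours=1.25, seed=20210930)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    cfg, patients = small_cohort
    feats = cohort_features(patients, first_hours=1.0)
    labels = binary_labels(patients)
    feats = feats.loc[[i for i in feats.index if i in labels]]
    return feats, labels


@pytest.fixture(scope="session")
def random_rr_series():
    """50 heterogeneous random RR series for oracle cross-checks."""
    rng = np.random.default_rng(1234)
    series = []
    for k in range(50):
        n = int(rng.integers(150, 450))
        base = rng.uniform(600.0, 1000.0)
        kind = k % 3
        if kind == 0:      # white noise around base
            rr = base + rng.normal(0, rng.uniform(10, 60), n)
        elif kind == 1:    # smooth oscillation + noise
            t = np.arange(n)
            rr = (base + rng.uniform(20, 60) * np.sin(2 * np.pi * t / rng.uniform(8, 40))
                  + rng.normal(0, 15, n))
        else:              # correlated random walk
            rr = base + np.cumsum(rng.normal(0, 8, n))
        rr = np.clip(rr, 300.0, 2000.0)
        series.append(rr)
    return series
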