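import numpy as np
import pandas as pd
import pytest

from bscore import BPDataset


def make_frame(values_by_subject, **extra):
    """Frame with one channel's values per subject; dbp = sbp - 40."""
    rows = []
    for subj, values in values_by_subject.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "subject_id": subj,
                    "time": float(i),
                    "sbp": float(v),
                    "dbp": float(v) - 40.0,
                    "heart_rate": 70.0,
                    "age": 50.0,
                    "sex": "female",
                    **extra,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_dataset():
    """Three subjects x three measurements (the minimum valid shape)."""
    return BPDataset(make_frame({"A": [120, 124, 128], "B": [100, 110, 120], "C": [80, 80, 80]}))


@pytest.fixture
def structured_cohort():
    """40 subjects x 50 rows where BP is exactly the calibration value."""
    rng = np.random.default_rng(0)
    ns, k = 40, 50
    base = rng.normal(120, 10, ns)
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:02d}" for i in range(ns)], k),
            "time": np.tile(np.arange(k, dtype=float), ns),
            "sbp": np.repeat(base, k),
            "dbp": np.repeat(base, k) - 40.0,
            "heart_rate": rng.normal(75, 5, ns * k),
            "age": np.repeat(rng.uniform(20, 70, ns).round(), k),
            "sex": np.repeat(np.where(rng.random(ns) < 0.5, "female", "male"), k),
        }
    )
    return BPDataset(frame)


@pytest.fixture
def noise_cohort():
    """2000 rows of pure i.i.d. noise (SD 10): nothing learnable."""
    rng = np.random.default_rng(1)
    n, per = 2000, 10
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:03d}" for i in range(n // per)], per),
            "time": np.tile(np.arange(per, dtype=float), n // per),
            "sbp": rng.normal(120, 10, n),
            "dbp": rng.normal(70, 5, n),
            "heart_rate": rng.normal(75, 5, n),
            "age": np.repeat(rng.uniform(20, 70, n // per).round(), per),
            "sex": np.repeat(np.where(rng.random(n // per) < 0.5, "female", "male"), per),
        }
    )
    return BPDataset(frame)
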