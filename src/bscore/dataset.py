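"""Containers for longitudinal blood-pressure data.

A :class:`BPDataset` is a thin, validated wrapper around a pandas DataFrame
with one row per measurement.  Rows are grouped by subject and sorted by
measurement time within each subject; the first measurement of every subject
is that subject's *calibration value*, the naive persistent predictor that
anchors the intrapersonal base performance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MeasurementRecord",
    "BPDataset",
    "ValidationReport",
    "validate_dataset",
]

#: Canonical column set of the tabular representation.
REQUIRED_COLUMNS = ("subject_id", "time", "sbp", "dbp", "heart_rate", "age", "sex")

@dataclass(frozen=True)
class MeasurementRecord:
    """One blood-pressure observation.

    ``time`` is in minutes (elapsed or since midnight, depending on source);
    pressures in mmHg, heart rate in beats/min, age in years, ``sex`` one of
    ``"female"``/``"male"``.
    """

    subject_id: str
    time: float
    sbp: float
    dbp: float
    heart_rate: float
    age: float
    sex: str

    def is_physiological(self) -> bool:
        """Systolic must exceed diastolic and both must be positive."""
        return self.sbp > self.dbp > 0


class BPDataset:
    """Ordered collection of BP measurements grouped by subject.

    Parameters
    ----------
    frame:
        DataFrame with the columns in :data:`REQUIRED_COLUMNS`.  Rows are
        re-sorted per subject by time (stable, so ties keep input order) and
        the original subject order of first appearance is preserved.
    channel:
        Which pressure channel (``"systolic"`` or ``"diastolic"``) the
        metric layer reads as the reference value.
    """

    def __init__(self, frame: pd.DataFrame, channel: str = "systolic") -> None:
        if channel not in ("systolic", "diastolic"):
            raise ValueError(f"channel must be 'systolic' or 'diastolic', got {channel!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        frame = frame.reset_index(drop=True)
        times = pd.to_numeric(frame["time"], errors="coerce")
        if not np.isfinite(times.to_numpy(dtype=float)).all():
            raise ValueError("non-finite or unparseable measurement times")
        frame = frame.assign(time=times.astype(float))
        # stable per-subject time sort; subjects keep first-appearance order
        order = pd.Categorical(frame["subject_id"], categories=frame["subject_id"].unique())
        frame = (
            frame.assign(_subj=order.codes)
            .sort_values(["_subj", "time"], kind="stable")
            .drop(columns="_subj")
            .reset_index(drop=True)
        )
        self.frame = frame
        self.channel = channel

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of measurement rows."""
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def channel_column(self) -> str:
        return "sbp" if self.channel == "systolic" else "dbp"

    @property
    def values(self) -> np.ndarray:
        """Reference values of the selected channel, in row order (mmHg)."""
        return self.frame[self.channel_column].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def calibration_values(self) -> np.ndarray:
        """Per-row broadcast of each subject's first (calibration) value."""
        col = self.frame[self.channel_column]
        return col.groupby(self.frame["subject_id"], sort=False).transform("first").to_numpy(dtype=float)

    def subject_counts(self) -> pd.Series:
        return self.frame.groupby("subject_id", sort=False).size()

    def with_channel(self, channel: str) -> "BPDataset":
        """Same data viewed through the other pressure channel."""
        out = object.__new__(BPDataset)
        out.frame = self.frame
        if channel not in ("systolic", "diastolic"):
            raise ValueError(f"channel must be 'systolic' or 'diastolic', got {channel!r}")
        out.channel = channel
        return out

    def nonphysiological_mask(self) -> np.ndarray:
        """Rows violating sbp > dbp > 0; flagged, never silently dropped."""
        sbp = self.frame["sbp"].to_numpy(dtype=float)
        dbp = self.frame["dbp"].to_numpy(dtype=float)
        return ~((sbp > dbp) & (dbp > 0))

    def records(self):
        for row in self.frame.itertuples(index=False):
            yield MeasurementRecord(
                subject_id=row.subject_id,
                time=float(row.time),
                sbp=float(row.sbp),
                dbp=float(row.dbp),
                heart_rate=float(row.heart_rate),
                age=float(row.age),
                sex=str(row.sex),
            )

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"BPDataset(n={self.n}, subjects={self.n_subjects}, channel={self.channel!r})"


@dataclass
class ValidationReport:
    """Outcome of the minimum-size rules for score calculation.

    ``valid`` is False when fewer than three subjects are present or any
    subject has fewer than three measurements (hard rule); ``warnings``
    carries the soft recommendation against datasets below 100 measurements.
    """

    valid: bool
    n_subjects: int
    n_measurements: int
    offending_subjects: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_dataset(dataset: BPDataset) -> ValidationReport:
    """Check a dataset against the minimum-size rules for the B-Score.

    At least 3 subjects with at least 3 measurements each are required; below
    100 total measurements a reliability warning is attached.
    """
    counts = dataset.subject_counts()
    offenders = counts.index[counts < 3].tolist()
    errors: list[str] = []
    warnings: list[str] = []
    if dataset.n_subjects < 3:
        errors.append(f"dataset has {dataset.n_subjects} subject(s); at least 3 are required")
    if offenders:
        errors.append(
            f"{len(offenders)} subject(s) have fewer than 3 measurements: "
            + ", ".join(str(s) for s in offenders[:10])
        )
    if not errors and dataset.n < 100:
        warnings.append(
            f"dataset has only {dataset.n} measurements; at least 100 are recommended "
            "for reliable scores"
        )
    n_flagged = int(dataset.nonphysiological_mask().sum())
    if n_flagged:
        warnings.append(f"{n_flagged} row(s) violate sbp > dbp > 0 (kept, flagged)")
    return ValidationReport(
        valid=not errors,
        n_subjects=dataset.n_subjects,
        n_measurements=dataset.n,
        offending_subjects=offenders,
        warnings=warnings,
        errors=errors,
    )
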