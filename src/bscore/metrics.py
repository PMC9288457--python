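"""Closed-form metric layer: RMSE variants, the B-Score and its inverse.

The B-Score expresses a model's test error (T-RMSE) relative to three base
performances of the dataset it was tested on:

* ``B1`` — interpersonal variability: RMSE of the cohort mean as a predictor,
  i.e. the population (1/n) standard deviation of the reference values;
* ``B2`` — intrapersonal variability: RMSE of each subject's first
  ("calibration") measurement as a persistent predictor;
* ``M``  — error of a deliberately minimalistic neural baseline
  (see :mod:`bscore.model`).

With all four in mmHg::

    B-Score = log10( sqrt( (B1 * M / T^2) * (B2 * M / T^2) ) )

The score is defined only when T is smaller than every base performance;
otherwise the canonical report is the literal string ``"B-Score < 0.00"``.
Higher scores mean better dataset-adjusted performance, and the formula is
invariant under rescaling of all four inputs, so the score is dimensionless
and comparable across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .dataset import BPDataset

__all__ = [
    "rmse",
    "t_rmse",
    "b1_rmse",
    "b2_rmse",
    "base_performances",
    "b_score_value",
    "b_score",
    "coequal_t_rmse",
    "format_b_score",
    "BasePerformances",
    "BScoreResult",
    "CoequalResult",
    "BELOW_ZERO_TEXT",
]

BELOW_ZERO_TEXT = "B-Score < 0.00"


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def rmse(predictions: Sequence[float], references: Sequence[float]) -> float:
    """Root mean squared error between predictions and reference values.

    Unlike the mean absolute error, the RMSE penalises inconsistent errors:
    a constant 4 mmHg error gives RMSE 4.0, while errors alternating between
    0 and 8 mmHg (same MAE) give RMSE ``sqrt(32) = 5.66``.
    """
    pred = _as_finite_array(predictions, "predictions")
    ref = _as_finite_array(references, "references")
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {ref.size} references")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def t_rmse(dataset: BPDataset, predictions: Sequence[float]) -> float:
    """Test-RMSE: RMSE of a model's predictions against the dataset's
    reference values for the selected channel, aligned by row order."""
    return rmse(predictions, dataset.values)


def b1_rmse(dataset: BPDataset) -> float:
    """Interpersonal variability: RMSE of the cohort mean as predictor.

    Equals the population (1/n denominator) standard deviation of the
    reference values — closely related to, but not identical with, the
    sample standard deviation.
    """
    vals = _as_finite_array(dataset.values, "reference values")
    return float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))


def b2_rmse(dataset: BPDataset) -> float:
    """Intrapersonal variability: RMSE of each subject's calibration value.

    Every row is compared against its subject's first measurement; the
    calibration rows themselves contribute zero error, keeping n identical
    across all base performances.
    """
    vals = _as_finite_array(dataset.values, "reference values")
    cal = dataset.calibration_values()
    return float(np.sqrt(np.mean((cal - vals) ** 2)))


@dataclass(frozen=True)
class BasePerformances:
    """The (B1, B2, M) triple in mmHg plus provenance metadata."""

    b1: float
    b2: float
    m: float
    n: int = 0
    channel: str = "systolic"
    m_repeats: int = 0
    m_repeat_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.b1, self.b2, self.m) < 0 or self.m_repeat_sd < 0:
            raise ValueError("base performances and repeat SD must be non-negative")

    def to_dict(self) -> dict:
        return {
            "b1": self.b1,
            "b2": self.b2,
            "m": self.m,
            "n": self.n,
            "channel": self.channel,
            "m_repeats": self.m_repeats,
            "m_repeat_sd": self.m_repeat_sd,
            "seed": self.seed,
        }


def base_performances(dataset: BPDataset, m: float, **meta) -> BasePerformances:
    """Bundle B1/B2 computed from ``dataset`` with an externally computed M."""
    return BasePerformances(
        b1=b1_rmse(dataset),
        b2=b2_rmse(dataset),
        m=m,
        n=dataset.n,
        channel=dataset.channel,
        **meta,
    )


@dataclass(frozen=True)
class BScoreResult:
    """A B-Score, or the below-zero classification when undefined.

    Exactly one of ``value`` / ``below_zero`` holds; ``formatted`` is the
    canonical two-decimal report string.
    """

    t_rmse: float
    base: BasePerformances
    value: Optional[float] = None
    below_zero: bool = False

    def __post_init__(self) -> None:
        if (self.value is None) == (not self.below_zero):
            raise ValueError("exactly one of value / below_zero must hold")

    @property
    def formatted(self) -> str:
        return format_b_score(self)

    def to_dict(self) -> dict:
        return {
            "b_score": self.value,
            "below_zero": self.below_zero,
            "t": self.t_rmse,
            "formatted": self.formatted,
            **self.base.to_dict(),
        }


def _check_positive(**named: float) -> None:
    for name, v in named.items():
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
        if v == 0:
            raise ZeroDivisionError(f"{name} = 0: B-Score undefined (log/ratio domain)")


def b_score_value(b1: float, b2: float, m: float, t: float) -> float:
    """Raw B-Score formula value, defined for any positive inputs.

    ``0.5*(log10 b1 + log10 b2) + log10 m - 2*log10 t`` — algebraically
    identical to ``log10(sqrt((b1*m/t^2)*(b2*m/t^2)))`` but numerically
    stable for extreme ratios.  Negative when t fails to beat the geometric
    combination of the bases.
    """
    _check_positive(b1=b1, b2=b2, m=m, t=t)
    return 0.5 * (np.log10(b1) + np.log10(b2)) + np.log10(m) - 2.0 * np.log10(t)


def b_score(
    b1: float,
    b2: float,
    m: float,
    t: float,
    base: Optional[BasePerformances] = None,
) -> BScoreResult:
    """Compute the B-Score with the defined-range reporting rule.

    The score carries a numeric value only when ``t`` is strictly smaller
    than every base performance; at or above any base the result is the
    below-zero classification (reported as ``"B-Score < 0.00"``).
    """
    _check_positive(b1=b1, b2=b2, m=m, t=t)
    if base is None:
        base = BasePerformances(b1=b1, b2=b2, m=m)
    if t >= min(b1, b2, m):
        return BScoreResult(t_rmse=t, base=base, below_zero=True)
    return BScoreResult(t_rmse=t, base=base, value=float(b_score_value(b1, b2, m, t)))


@dataclass(frozen=True)
class CoequalResult:
    """T-RMSE needed on a dataset to reach a target B-Score.

    ``attainable`` is False when the required T-RMSE is not smaller than
    every base performance, i.e. the target score has no defined-score
    solution on this dataset (any sufficiently small error then outperforms
    the reference system outright).
    """

    t: float
    target_score: float
    attainable: bool


def coequal_t_rmse(b1: float, b2: float, m: float, target_score: float) -> CoequalResult:
    """Invert the B-Score: the T-RMSE achieving ``target_score`` on a dataset
    with base performances (b1, b2, m).

    Closed form ``t = 10**((0.5*(log10 b1 + log10 b2) + log10 m - S) / 2)``;
    round-trips with :func:`b_score` to better than 1e-9 relative.
    """
    _check_positive(b1=b1, b2=b2, m=m)
    if not np.isfinite(target_score):
        raise ValueError("target_score must be finite")
    exponent = (0.5 * (np.log10(b1) + np.log10(b2)) + np.log10(m) - target_score) / 2.0
    t = float(10.0 ** exponent)
    return CoequalResult(t=t, target_score=float(target_score), attainable=t < min(b1, b2, m))


def format_b_score(result: BScoreResult | float) -> str:
    """Canonical report string: two decimals, half-up rounding; undefined
    scores render as ``"B-Score < 0.00"``."""
    if isinstance(result, BScoreResult):
        if result.below_zero:
            return BELOW_ZERO_TEXT
        value = result.value
    else:
        value = float(result)
    return str(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
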