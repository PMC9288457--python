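"""Minimalistic neural baseline whose out-of-fold error is the M-RMSE.

The baseline answers "how easy is it to build a decent BP estimator for
this dataset using only covariates every BP dataset has": age, sex, time of
measurement, heart rate, a single calibration BP with its time and heart
rate, and the cohort mean.  Its architecture is fixed — a five-layer
feed-forward network (four hidden layers, one linear output) with ReLU
activations, dropout and an L2 weight penalty — and is retrained from
scratch for every dataset and channel.

The M-RMSE is computed by subject-level k-fold cross-validation: subjects
(never rows) are shuffled into folds, the network is trained on the
remaining folds and predicts the held-out fold, and the pooled out-of-fold
predictions yield one RMSE.  Depending on dataset size the whole procedure
is repeated with reshuffled folds and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import BPDataset
from .metrics import rmse

__all__ = [
    "MinimalModelConfig",
    "FEATURE_COLUMNS",
    "build_features",
    "repeat_schedule",
    "MinimalBPRegressor",
    "MRmseResult",
    "m_rmse",
]

MINUTES_PER_DAY = 1440.0

#: Order of the feature matrix columns produced by :func:`build_features`.
FEATURE_COLUMNS = (
    "age",
    "sex_code",
    "tod_sin",
    "tod_cos",
    "elapsed_since_calibration",
    "heart_rate",
    "calibration_bp",
    "calibration_tod_sin",
    "calibration_tod_cos",
    "calibration_heart_rate",
    "cohort_mean",
)

_SEX_CODES = {"female": 0.0, "male": 1.0, "f": 0.0, "m": 1.0, "0": 0.0, "1": 1.0}


@dataclass
class MinimalModelConfig:
    """Hyperparameters of the minimal baseline.

    Defaults: hidden widths [64, 64, 32, 16] (five layers counting the
    linear output), dropout 0.2 after each hidden layer, L2 penalty 1e-3,
    Adam with learning rate 1e-3, batches of 256, up to 200 epochs with
    patience-20 early stopping on a 10% inner validation split, 5 folds.
    """

    hidden_layer_sizes: tuple = (64, 64, 32, 16)
    dropout_rate: float = 0.2
    l2_strength: float = 1e-3
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stop_patience: int = 20
    k_folds: int = 5
    batch_size: int = 256
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        for name in ("learning_rate", "max_epochs", "early_stop_patience", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(h <= 0 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")


def _time_of_day_encoding(time_minutes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    frac = np.mod(time_minutes, MINUTES_PER_DAY) / MINUTES_PER_DAY
    return np.sin(2 * np.pi * frac), np.cos(2 * np.pi * frac)


def _encode_sex(sex: pd.Series) -> np.ndarray:
    codes = sex.astype(str).str.strip().str.lower().map(_SEX_CODES)
    if codes.isna().any():
        bad = sex[codes.isna()].unique()[:5]
        raise ValueError(f"unrecognised sex value(s): {list(bad)}; expected female/male")
    return codes.to_numpy(dtype=float)


def build_features(dataset: BPDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table and target vector for the minimal baseline.

    One row per measurement, aligned with the dataset's row order.  The
    calibration columns (first measurement's BP, time-of-day encoding, heart
    rate) are constant within a subject; the cohort mean is constant across
    the dataset.  Time of day is encoded on the unit circle so midnight and
    23:59 are neighbours.  Features are returned unscaled — standardisation
    with training-fold statistics happens inside the estimator.
    """
    frame = dataset.frame
    for col in ("age", "sex", "heart_rate", "time"):
        if frame[col].isna().any():
            raise ValueError(f"column '{col}' contains missing values")
    y = dataset.values
    times = frame["time"].to_numpy(dtype=float)
    tod_sin, tod_cos = _time_of_day_encoding(times)

    grp = frame.groupby("subject_id", sort=False)
    cal_time = grp["time"].transform("first").to_numpy(dtype=float)
    cal_bp = dataset.calibration_values()
    cal_hr = grp["heart_rate"].transform("first").to_numpy(dtype=float)
    cal_sin, cal_cos = _time_of_day_encoding(cal_time)

    features = pd.DataFrame(
        {
            "age": frame["age"].to_numpy(dtype=float),
            "sex_code": _encode_sex(frame["sex"]),
            "tod_sin": tod_sin,
            "tod_cos": tod_cos,
            "elapsed_since_calibration": times - cal_time,
            "heart_rate": frame["heart_rate"].to_numpy(dtype=float),
            "calibration_bp": cal_bp,
            "calibration_tod_sin": cal_sin,
            "calibration_tod_cos": cal_cos,
            "calibration_heart_rate": cal_hr,
            "cohort_mean": np.full(len(frame), y.mean()),
        },
        columns=list(FEATURE_COLUMNS),
    )
    return features, y


def repeat_schedule(n: int) -> tuple[int, int]:
    """(k_folds, n_repeats) as a function of dataset size.

    Small datasets are reshuffled and averaged more to stabilise the
    estimate; very large datasets need a single pass.  k is always 5.
    """
    if n < 9:
        raise ValueError("dataset too small for the repeat schedule (n >= 9)")
    if n < 5_000:
        return 5, 10
    if n < 500_000:
        return 5, 3
    return 5, 1


# ----------------------------------------------------------------------
# the network core
# ----------------------------------------------------------------------
class _MLPCore:
    """Plain-numpy feed-forward regressor: ReLU, inverted dropout, L2, Adam."""

    def __init__(self, n_features, hidden, dropout, l2, lr, rng):
        self.dropout = dropout
        self.l2 = l2
        self.lr = lr
        sizes = [n_features, *hidden, 1]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(v) for v in self.b]
        self._vb = [np.zeros_like(v) for v in self.b]
        self._step = 0

    def forward(self, X, rng=None):
        """Returns predictions and, when training (rng given), the cache."""
        a = X
        cache = []
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = a @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            mask = None
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        out = (a @ self.W[-1] + self.b[-1]).ravel()
        cache.append((a, None, None))
        return out, cache

    def train_batch(self, X, y, rng):
        pred, cache = self.forward(X, rng=rng)
        n = len(y)
        loss = float(np.mean((pred - y) ** 2))
        delta = (2.0 / n) * (pred - y)[:, None]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        a_last = cache[-1][0]
        gW[-1] = a_last.T @ delta + self.l2 * self.W[-1]
        gb[-1] = delta.sum(axis=0)
        grad_a = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            a_in, z, mask = cache[i]
            if mask is not None:
                grad_a = grad_a * mask
            grad_z = grad_a * (z > 0)
            gW[i] = a_in.T @ grad_z + self.l2 * self.W[i]
            gb[i] = grad_z.sum(axis=0)
            if i > 0:
                grad_a = grad_z @ self.W[i].T
        self._adam(gW, gb)
        return loss

    def _adam(self, gW, gb, beta1=0.9, beta2=0.999, eps=1e-8):
        self._step += 1
        t = self._step
        corr1 = 1.0 - beta1**t
        corr2 = 1.0 - beta2**t
        for i in range(len(self.W)):
            for param, grad, m, v in (
                (self.W[i], gW[i], self._mW[i], self._vW[i]),
                (self.b[i], gb[i], self._mb[i], self._vb[i]),
            ):
                m *= beta1
                m += (1 - beta1) * grad
                v *= beta2
                v += (1 - beta2) * grad**2
                param -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)

    def get_weights(self):
        return [w.copy() for w in self.W], [v.copy() for v in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [v.copy() for v in b]


class MinimalBPRegressor(RegressorMixin, BaseEstimator):
    """The fixed minimal baseline as a scikit-learn estimator.

    A five-layer feed-forward network (hidden widths ``hidden_layer_sizes``
    plus a linear output) with ReLU activations, inverted dropout after each
    hidden layer, an L2 weight penalty and Adam optimisation.  Inputs and
    targets are standardised internally with statistics of the fit data, so
    cross-validation never leaks held-out rows into the scaling.

    Training stops early when the loss on an inner validation split (a
    ``validation_fraction`` share of the fit data) has not improved for
    ``early_stop_patience`` epochs; the best-validation weights are kept.
    A non-finite training loss triggers one re-initialised retry before
    raising.

    Parameters mirror :class:`MinimalModelConfig`.  Deterministic given
    ``random_state``.
    """

    def __init__(
        self,
        hidden_layer_sizes=(64, 64, 32, 16),
        dropout_rate=0.2,
        l2_strength=1e-3,
        learning_rate=1e-3,
        max_epochs=200,
        early_stop_patience=20,
        batch_size=256,
        validation_fraction=0.1,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout_rate = dropout_rate
        self.l2_strength = l2_strength
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        seed = self.random_state if self.random_state is not None else 0
        root = np.random.SeedSequence(entropy=int(seed))
        for attempt, child in enumerate(root.spawn(2)):
            rng = np.random.Generator(np.random.PCG64(child))
            try:
                self._fit_once(X, y, rng)
                return self
            except FloatingPointError:
                if attempt == 1:
                    raise RuntimeError(
                        "training diverged (non-finite loss) twice; check inputs"
                    ) from None
        return self  # pragma: no cover

    def _fit_once(self, X, y, rng):
        self._x_scaler = StandardScaler().fit(X)
        Xs = self._x_scaler.transform(X)
        self._y_mean = float(np.mean(y))
        self._y_scale = float(np.std(y)) or 1.0
        ys = (y - self._y_mean) / self._y_scale

        n = len(ys)
        n_val = max(1, int(round(self.validation_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = Xs[tr_idx], ys[tr_idx]
        Xval, yval = Xs[val_idx], ys[val_idx]

        net = _MLPCore(
            Xs.shape[1],
            tuple(self.hidden_layer_sizes),
            self.dropout_rate,
            self.l2_strength,
            self.learning_rate,
            rng,
        )
        batch = min(self.batch_size, len(ytr))
        best_val = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(ytr))
            for start in range(0, len(ytr), batch):
                idx = order[start : start + batch]
                loss = net.train_batch(Xtr[idx], ytr[idx], rng)
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
            if n_val:
                val_pred, _ = net.forward(Xval)
                val_loss = float(np.mean((val_pred - yval) ** 2))
            else:
                tr_pred, _ = net.forward(Xtr)
                val_loss = float(np.mean((tr_pred - ytr) ** 2))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = net.get_weights()
                best_epoch = epoch
            elif epoch - best_epoch >= self.early_stop_patience:
                break
        net.set_weights(best_weights)
        self._net = net
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = epoch + 1
        self.validation_loss_ = best_val

    def predict(self, X):
        check_is_fitted(self, "_net")
        X = check_array(X)
        Xs = self._x_scaler.transform(X)
        pred, _ = self._net.forward(Xs)
        return pred * self._y_scale + self._y_mean


@dataclass
class MRmseResult:
    """Outcome of the repeated k-fold M-RMSE evaluation.

    ``m`` is the mean of the per-repeat out-of-fold RMSEs; ``repeat_sd``
    their population standard deviation (0 for a single repeat).
    """

    m: float
    per_repeat: list = field(default_factory=list)
    repeat_sd: float = 0.0
    n_repeats: int = 1
    k_folds: int = 5
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "per_repeat": list(self.per_repeat),
            "repeat_sd": self.repeat_sd,
            "n_repeats": self.n_repeats,
            "k_folds": self.k_folds,
            "seed": self.seed,
        }


def _subject_folds(subject_ids: np.ndarray, k: int, rng: np.random.Generator):
    """Shuffle subjects (not rows) into k roughly equal folds; yield row
    index arrays of each held-out fold."""
    subjects = pd.unique(subject_ids)
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold evaluation")
    shuffled = subjects[rng.permutation(len(subjects))]
    fold_of_subject = {s: i % k for i, s in enumerate(shuffled)}
    fold_of_row = np.array([fold_of_subject[s] for s in subject_ids])
    for fold in range(k):
        yield np.flatnonzero(fold_of_row == fold)


def m_rmse(
    dataset: BPDataset,
    config: Optional[MinimalModelConfig] = None,
    seed: int = 0,
    n_repeats: Optional[int] = None,
) -> MRmseResult:
    """M-RMSE of a dataset: out-of-fold error of the minimal baseline.

    For each repeat, subjects are reshuffled into ``config.k_folds`` folds;
    the network is trained on the other folds and predicts the held-out
    fold, so every row receives exactly one out-of-fold prediction per
    repeat.  The per-repeat RMSEs are averaged.  ``n_repeats`` defaults to
    the size-dependent schedule of :func:`repeat_schedule`.

    Deterministic given (dataset, config, seed): one master seed fans out to
    per-repeat fold shuffles and per-fold weight initialisation via a
    deterministic counter scheme.
    """
    config = config or MinimalModelConfig()
    features, y = build_features(dataset)
    X = features.to_numpy(dtype=float)
    subject_ids = dataset.subject_ids
    if n_repeats is None:
        _, n_repeats = repeat_schedule(dataset.n)
    k = config.k_folds

    per_repeat: list[float] = []
    for rep in range(n_repeats):
        fold_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), rep])))
        oof = np.full(len(y), np.nan)
        for fold_idx, test_rows in enumerate(_subject_folds(subject_ids, k, fold_rng)):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_rows] = False
            child_seed = int(
                np.random.SeedSequence([int(seed), rep, fold_idx]).generate_state(1)[0] % (2**31)
            )
            est = MinimalBPRegressor(
                hidden_layer_sizes=config.hidden_layer_sizes,
                dropout_rate=config.dropout_rate,
                l2_strength=config.l2_strength,
                learning_rate=config.learning_rate,
                max_epochs=config.max_epochs,
                early_stop_patience=config.early_stop_patience,
                batch_size=config.batch_size,
                validation_fraction=config.validation_fraction,
                random_state=child_seed,
            )
            est.fit(X[train_mask], y[train_mask])
            oof[test_rows] = est.predict(X[test_rows])
        if np.isnan(oof).any():  # pragma: no cover - fold partition guarantee
            raise RuntimeError("some rows received no out-of-fold prediction")
        per_repeat.append(rmse(oof, y))

    m = float(np.mean(per_repeat))
    sd = float(np.std(per_repeat)) if len(per_repeat) > 1 else 0.0
    return MRmseResult(
        m=m,
        per_repeat=per_repeat,
        repeat_sd=sd,
        n_repeats=n_repeats,
        k_folds=k,
        seed=int(seed),
    )
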