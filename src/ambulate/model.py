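"""Shallow neural classifier for per-epoch ambulatory status.

The model is a two-dense-layer network (one hidden ReLU layer, one softmax
output layer) trained with Adam at learning rate 0.001, batch size 32,
categorical cross-entropy loss, for 10 passes over the shuffled training
data. Features are z-scored by training-set statistics. The network is
implemented directly in NumPy: at 14 inputs and a few dozen hidden units
there is nothing for a deep-learning framework to add, and a from-scratch
implementation keeps training bit-reproducible under a fixed seed.

The operating point is not 0.5: the decision threshold is tuned to
minimize the mean absolute percentage error (MAPE) of *daily ambulatory
minutes* under participant-level 5-fold cross-validation, pooling held-out
predictions from all folds and grid-searching the threshold on the pooled
data (see :func:`optimize_threshold`).

:class:`AmbulatoryStatusClassifier` follows the scikit-learn estimator
protocol (``fit`` / ``predict_proba`` / ``predict``, ``get_params`` /
``set_params``, trailing-underscore fitted attributes) and composes with
sklearn model-selection utilities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FEATURE_NAMES

N_FEATURES = len(FEATURE_NAMES)
DEFAULT_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _AdamState:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train_network(X, Y, hidden_units, batch_size, learning_rate,
                   training_epochs, seed):
    """Adam / cross-entropy training loop; returns (W1, b1, W2, b2)."""
    n, d = X.shape
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, hidden_units))
    b1 = np.zeros(hidden_units)
    W2 = rng.normal(0.0, np.sqrt(2.0 / hidden_units), size=(hidden_units, 2))
    b2 = np.zeros(2)
    params = [W1, b1, W2, b2]
    adam = _AdamState([p.shape for p in params], learning_rate)

    for _ in range(training_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = X[idx], Y[idx]
            h_pre = xb @ W1 + b1
            h = np.maximum(h_pre, 0.0)
            p = _softmax(h @ W2 + b2)
            # gradient of mean categorical cross-entropy
            dz2 = (p - yb) / len(idx)
            gW2 = h.T @ dz2
            gb2 = dz2.sum(axis=0)
            dh = dz2 @ W2.T
            dh[h_pre <= 0] = 0.0
            gW1 = xb.T @ dh
            gb1 = dh.sum(axis=0)
            adam.step(params, [gW1, gb1, gW2, gb2])
    return W1, b1, W2, b2


@dataclass
class CvThresholdTrace:
    """Record of the cross-validated threshold grid search."""

    grid: np.ndarray
    pooled_mape_per_threshold: np.ndarray  # percent
    chosen_threshold: float
    fold_assignment: dict[str, int]  # participant_id -> fold in 1..5
    n_zero_reference_days: int = 0


class AmbulatoryStatusClassifier(BaseEstimator, ClassifierMixin):
    """Two-dense-layer ambulatory-status classifier for 10-second epochs.

    Parameters
    ----------
    hidden_units : int, default 32
        Width of the single hidden ReLU layer.
    batch_size : int, default 32
        Mini-batch size for Adam.
    learning_rate : float, default 0.001
        Adam step size.
    training_epochs : int, default 10
        Passes over the shuffled training data.
    random_state : int, default 0
        Seed controlling weight init and batch shuffling; training is
        bit-reproducible for a fixed seed.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; the larger one is the positive (ambulatory)
        class when labels are {0, 1}.
    normalization_mean_, normalization_std_ : ndarray of shape (14,)
        Per-feature z-scoring constants from the training data.
    layer1_weights_, layer1_bias_, layer2_weights_, layer2_bias_ : ndarray
        Network parameters.
    threshold_ : float or None
        Operating threshold on the ambulatory-class probability; ``None``
        until set via :meth:`optimize_threshold` or :meth:`set_threshold`.
    training_fingerprint_ : str
        SHA-256 digest of the config and training data.
    """

    def __init__(self, hidden_units: int = 32, batch_size: int = 32,
                 learning_rate: float = 0.001, training_epochs: int = 10,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.training_epochs = training_epochs
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"need exactly 2 classes in y, got {len(classes)}: {classes}")
        self.classes_ = classes
        ybin = (y == classes[1]).astype(int)

        mean = X.mean(axis=0)
        std = X.std(axis=0)
        constant = np.flatnonzero(std == 0)
        if len(constant):
            names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
                     for i in constant]
            raise ValueError(f"constant feature column(s): {', '.join(names)}")
        Xz = (X - mean) / std
        Y = np.eye(2)[ybin]

        self.normalization_mean_ = mean
        self.normalization_std_ = std
        W1, b1, W2, b2 = _train_network(
            Xz, Y, self.hidden_units, self.batch_size, self.learning_rate,
            self.training_epochs, self.random_state)
        self.layer1_weights_, self.layer1_bias_ = W1, b1
        self.layer2_weights_, self.layer2_bias_ = W2, b2
        self.threshold_ = None
        self.n_features_in_ = N_FEATURES

        h = hashlib.sha256()
        h.update(repr(self.get_params(deep=False)).encode())
        h.update(np.ascontiguousarray(X).tobytes())
        h.update(np.ascontiguousarray(ybin).tobytes())
        self.training_fingerprint_ = h.hexdigest()
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities (columns ordered as ``classes_``)."""
        check_is_fitted(self, "layer1_weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        Xz = (X - self.normalization_mean_) / self.normalization_std_
        h = np.maximum(Xz @ self.layer1_weights_ + self.layer1_bias_, 0.0)
        return _softmax(h @ self.layer2_weights_ + self.layer2_bias_)

    def predict_scores(self, X) -> np.ndarray:
        """Ambulatory-class (positive-class) probabilities in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Binary predictions at the tuned operating threshold.

        Requires ``threshold_`` to be set (via :meth:`optimize_threshold`
        or :meth:`set_threshold`); the operating point is part of the
        validated algorithm, so no silent 0.5 default is applied.
        """
        check_is_fitted(self, "layer1_weights_")
        if getattr(self, "threshold_", None) is None:
            raise ValueError(
                "decision threshold not set; run optimize_threshold() or "
                "set_threshold() before predict()")
        scores = self.predict_scores(X)
        return self.classes_[(scores >= self.threshold_).astype(int)]

    def set_threshold(self, threshold: float):
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {threshold}")
        check_is_fitted(self, "layer1_weights_")
        self.threshold_ = float(threshold)
        return self

    # -- threshold optimization -------------------------------------------

    def optimize_threshold(self, X, y, participant_ids, day_ids,
                           reference_minutes: dict, grid=None,
                           n_folds: int = 5) -> CvThresholdTrace:
        """Tune the decision threshold by cross-validated daily MAPE.

        Participants are shuffled (seeded) and dealt round-robin into
        ``n_folds`` folds. For each fold a fresh network with this
        estimator's configuration is trained on the remaining folds and
        scores the held-out fold's epochs. Pooling held-out scores across
        all folds, each grid threshold is converted to predicted daily
        ambulatory minutes per participant-day and scored by MAPE against
        ``reference_minutes[(participant_id, day_id)]``; the smallest
        threshold attaining the minimum pooled MAPE is chosen and stored
        in ``threshold_``. Participant-days with zero reference minutes
        are excluded from the MAPE (their percentage error is undefined)
        and counted in the trace.
        """
        check_is_fitted(self, "layer1_weights_")
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        pids = np.asarray([str(p) for p in participant_ids])
        days = np.asarray(day_ids)
        unique_pids = np.unique(pids)
        if len(unique_pids) < n_folds:
            raise ValueError(
                f"threshold optimization needs >= {n_folds} participants, "
                f"got {len(unique_pids)}")

        rng = np.random.default_rng(self.random_state)
        shuffled = unique_pids.copy()
        rng.shuffle(shuffled)
        fold_of = {p: (i % n_folds) + 1 for i, p in enumerate(shuffled)}

        pooled_scores = np.empty(len(X))
        for f in range(1, n_folds + 1):
            held = np.isin(pids, [p for p in unique_pids if fold_of[p] == f])
            fold_model = clone(self)
            fold_model.random_state = self.random_state + f
            fold_model.fit(X[~held], y[~held])
            pooled_scores[held] = fold_model.predict_scores(X[held])

        mape, n_zero = pooled_daily_mape(
            pooled_scores, pids, days, reference_minutes, grid)
        best = int(np.flatnonzero(mape == mape.min())[0])
        chosen = float(grid[best])
        self.threshold_ = chosen
        return CvThresholdTrace(grid=grid, pooled_mape_per_threshold=mape,
                                chosen_threshold=chosen,
                                fold_assignment=fold_of,
                                n_zero_reference_days=n_zero)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize the fitted model (weights, normalization, threshold)."""
        check_is_fitted(self, "layer1_weights_")
        doc = {
            "config": self.get_params(deep=False),
            "classes": np.asarray(self.classes_).tolist(),
            "normalization_mean": self.normalization_mean_.tolist(),
            "normalization_std": self.normalization_std_.tolist(),
            "layer1_weights": self.layer1_weights_.tolist(),
            "layer1_bias": self.layer1_bias_.tolist(),
            "layer2_weights": self.layer2_weights_.tolist(),
            "layer2_bias": self.layer2_bias_.tolist(),
            "threshold": self.threshold_,
            "training_fingerprint": self.training_fingerprint_,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AmbulatoryStatusClassifier":
        doc = json.loads(text)
        model = cls(**doc["config"])
        model.classes_ = np.asarray(doc["classes"])
        model.normalization_mean_ = np.asarray(doc["normalization_mean"])
        model.normalization_std_ = np.asarray(doc["normalization_std"])
        model.layer1_weights_ = np.asarray(doc["layer1_weights"])
        model.layer1_bias_ = np.asarray(doc["layer1_bias"])
        model.layer2_weights_ = np.asarray(doc["layer2_weights"])
        model.layer2_bias_ = np.asarray(doc["layer2_bias"])
        model.threshold_ = doc["threshold"]
        model.training_fingerprint_ = doc["training_fingerprint"]
        model.n_features_in_ = N_FEATURES
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "AmbulatoryStatusClassifier":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def pooled_daily_mape(scores, participant_ids, day_ids, reference_minutes,
                      grid) -> tuple[np.ndarray, int]:
    """Daily-MAPE-vs-threshold curve for pooled epoch scores.

    For each threshold t, an epoch is predicted ambulatory iff its score
    >= t; predicted daily minutes are 10 s x count / 60 per participant-day.
    Returns (MAPE percent per grid point, number of zero-reference days
    excluded).
    """
    scores = np.asarray(scores, dtype=float)
    keys = pd.MultiIndex.from_arrays(
        [np.asarray(participant_ids), np.asarray(day_ids)])
    codes, uniques = pd.factorize(keys)
    grid = np.asarray(grid, dtype=float)

    refs = np.array([reference_minutes.get(tuple(k), np.nan) for k in uniques])
    n_zero = int(np.sum(refs == 0))
    valid = np.isfinite(refs) & (refs > 0)
    if not valid.any():
        raise ValueError("no participant-days with positive reference minutes")

    # per-day sorted scores -> predicted count at t via searchsorted
    pred_minutes = np.zeros((len(uniques), len(grid)))
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    sorted_scores = scores[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(scores)]))
    for s, e in zip(starts, ends):
        day_scores = np.sort(sorted_scores[s:e])
        counts = len(day_scores) - np.searchsorted(day_scores, grid, side="left")
        pred_minutes[sorted_codes[s], :] = counts * 10.0 / 60.0

    ape = np.abs(pred_minutes[valid] - refs[valid, None]) / refs[valid, None]
    return ape.mean(axis=0) * 100.0, n_zero


def classify_epochs(model: AmbulatoryStatusClassifier, X) -> np.ndarray:
    """Binary predictions at the model's tuned threshold (>= convention)."""
    return model.predict(X)
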