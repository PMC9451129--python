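"""Per-station interpretation decoders.

Seven L2-regularized logistic-regression classifiers (one per station,
lbfgs solver, C = 1 by default) map a station's activity pattern to
p(c), the probability that the listener currently holds the cheating
interpretation; the paranoid probability is exactly 1 - p(c).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import TrainingError
from .rngs import CHEATING

DEFAULT_C = 1.0


@dataclass(frozen=True)
class StationModel:
    """Fitted linear decoder for one station."""

    station_index: int
    weights: np.ndarray
    intercept: float
    regularization_c: float = DEFAULT_C
    training_digest: str = ""

    def __post_init__(self) -> None:
        if self.regularization_c <= 0:
            raise ValueError("regularization_c must be positive")


def _feature_columns(training_set: pd.DataFrame) -> list[str]:
    cols = [c for c in training_set.columns if c.startswith("f") and c[1:].isdigit()]
    if not cols:
        raise ValueError("training set has no feature columns f0..fN")
    return sorted(cols, key=lambda c: int(c[1:]))


def _digest(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:12]


def train_station_models(
    training_set: pd.DataFrame, regularization_c: float = DEFAULT_C
) -> list[StationModel]:
    """Fit one logistic decoder per station from a labeled pattern table.

    ``training_set`` is long-format with columns participant, group,
    run, station, f0..fN (see :func:`storynf.cohort.generate_training_cohort`).
    The cheating group is coded 1 so the positive-class probability is
    p(c).  The objective is convex, so the fit is deterministic given
    the data.
    """
    if regularization_c <= 0:
        raise ValueError("regularization_c must be positive")
    feat_cols = _feature_columns(training_set)
    models = []
    for station, block in training_set.groupby("station", sort=True):
        y = (block["group"] == CHEATING).to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError(f"station {station}: training data contain a single class")
        X = block[feat_cols].to_numpy(dtype=float)
        clf = LogisticRegression(
            C=regularization_c, solver="lbfgs", tol=1e-10, max_iter=10_000
        )
        clf.fit(X, y)
        models.append(
            StationModel(
                station_index=int(station),
                weights=clf.coef_[0].copy(),
                intercept=float(clf.intercept_[0]),
                regularization_c=float(regularization_c),
                training_digest=_digest(X, y),
            )
        )
    return models


def predict_cheating_probability(model: StationModel, pattern: np.ndarray) -> float:
    """p(c) = logistic(weights . pattern + intercept).

    The paranoid probability is exactly 1 - p(c).
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != model.weights.shape:
        raise ValueError(
            f"pattern length {pattern.size} does not match model dimension {model.weights.size}"
        )
    z = float(model.weights @ pattern + model.intercept)
    # numerically stable logistic
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(-z)))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))
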