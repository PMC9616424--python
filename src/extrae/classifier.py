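"""Supervised component: a random-forest relevance classifier over rule features.

Defaults are frozen explicitly rather than inherited from any toolkit:
100 trees, unlimited depth, square-root feature sampling per split,
bootstrap resampling, no out-of-bag scoring, fixed seed.  The relevance
score of a rule is the forest's probability for the relevant class
(with fully grown trees this equals the fraction of trees voting
relevant); the hard label is score >= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES

DEFAULT_HYPERPARAMS: dict[str, Any] = {
    "n_estimators": 100,
    "max_depth": None,
    "max_features": "sqrt",
    "bootstrap": True,
    "oob_score": False,
}


@dataclass
class RelevanceModel:
    """A trained relevance classifier plus the metadata needed to reuse it."""

    estimator: RandomForestClassifier | None
    feature_order: tuple[str, ...]
    training_size: int
    rng_seed: int
    constant_label: bool | None = None  # set when training data had one class

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "RelevanceModel":
        model = joblib.load(path)
        if not isinstance(model, RelevanceModel):
            raise TypeError(f"{path} does not contain a RelevanceModel")
        return model


def _as_matrix(features: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix of rule vectors")
    return X


def train(
    features: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[bool],
    hyperparams: Mapping[str, Any] | None = None,
    rng_seed: int = 0,
    feature_order: Sequence[str] = FEATURE_NAMES,
) -> RelevanceModel:
    """Fit the relevance forest; deterministic given ``rng_seed``."""
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=bool)
    if len(X) != len(y):
        raise ValueError(f"features/labels length mismatch: {len(X)} vs {len(y)}")
    if len(X) == 0:
        raise ValueError("cannot train on an empty set")
    if X.shape[1] != len(feature_order):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns, expected {len(feature_order)}"
        )
    params = dict(DEFAULT_HYPERPARAMS)
    params.update(hyperparams or {})
    if len(np.unique(y)) < 2:
        warnings.warn(
            "training labels contain a single class; model predicts it everywhere",
            stacklevel=2,
        )
        return RelevanceModel(
            estimator=None,
            feature_order=tuple(feature_order),
            training_size=len(X),
            rng_seed=rng_seed,
            constant_label=bool(y[0]),
        )
    forest = RandomForestClassifier(random_state=rng_seed, **params)
    forest.fit(X, y)
    return RelevanceModel(
        estimator=forest,
        feature_order=tuple(feature_order),
        training_size=len(X),
        rng_seed=rng_seed,
    )


def predict(
    model: RelevanceModel, features: Sequence[Sequence[float]] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-rule (label, score) with score in [0, 1] and label = score >= 0.5."""
    X = _as_matrix(features)
    if X.shape[1] != len(model.feature_order):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns, model expects "
            f"{len(model.feature_order)}"
        )
    if model.estimator is None:
        score = float(model.constant_label)
        scores = np.full(len(X), score, dtype=float)
    else:
        proba = model.estimator.predict_proba(X)
        relevant_col = list(model.estimator.classes_).index(True)
        scores = proba[:, relevant_col]
    return scores >= 0.5, scores
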