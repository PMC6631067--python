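"""Discrete AdaBoost over decision stumps, metrics and stratified K-fold CV.

The ensemble hypothesis is E(x) = sum_i k_i(x) * rho_i, a weighted vote
of depth-1 threshold stumps k_i on single features; the predicted label
is sign(E).  Training is the classical discrete AdaBoost loop: at each
round an exhaustive search over features x candidate thresholds x
polarities picks the stump minimizing the weighted 0/1 error, the stump
gets weight rho = 0.5 * ln((1 - err) / err), and example weights are
re-scaled by exp(-rho * y * k(x)).  Rounds stop early when a stump is
perfect (err = 0) or no stump beats chance (err >= 0.5).

Candidate thresholds are midpoints between consecutive sorted unique
feature values; ties between equally good stumps break to the lowest
feature index, then the smallest threshold, then polarity +1.

A statsmodels-style surface is provided on top of the functional API:
``HeartSoundBooster(features, labels).fit()`` returns a
:class:`BoosterResults` carrying the stump table, training diagnostics
and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BadInputError, DegenerateDataError
from .features import FeatureMatrix

_PERFECT_ERR = 1e-12  # stands in for err = 0 in the log-odds weight


@dataclass(frozen=True)
class WeakHypothesis:
    """Decision stump: predict sign(polarity * (x[feature] - threshold)).

    sign(0) is mapped to +1.
    """

    feature_index: int
    threshold: float
    polarity: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.polarity * (X[:, self.feature_index] - self.threshold)
        return np.where(z >= 0, 1, -1)


@dataclass
class EnsembleModel:
    """Weighted stump ensemble E(x) = sum_i k_i(x) * rho_i."""

    hypotheses: list
    weights: np.ndarray
    H: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.hypotheses) != self.weights.size:
            raise BadInputError("hypotheses and weights disagree")
        if len(self.hypotheses) > self.H:
            raise BadInputError("more hypotheses than rounds")
        if self.weights.size and (
            not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0)
        ):
            raise BadInputError("hypothesis weights must be finite and positive")

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Raw ensemble sum E(x) per row."""
        X = np.asarray(X, dtype=float)
        if not self.hypotheses:
            raise BadInputError("empty ensemble")
        out = np.zeros(X.shape[0])
        for h, w in zip(self.hypotheses, self.weights):
            out += w * h.predict(X)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels sign(E(x)), with sign(0) -> +1."""
        return np.where(self.margin(X) >= 0, 1, -1)

    def to_json(self, path=None) -> str:
        payload = {
            "rounds": self.H,
            "stumps": [
                {
                    "feature_index": h.feature_index,
                    "threshold": h.threshold,
                    "polarity": h.polarity,
                    "weight": float(w),
                }
                for h, w in zip(self.hypotheses, self.weights)
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            payload = json.load(fh)
        stumps = [
            WeakHypothesis(s["feature_index"], s["threshold"], s["polarity"])
            for s in payload["stumps"]
        ]
        weights = np.array([s["weight"] for s in payload["stumps"]], dtype=float)
        return cls(hypotheses=stumps, weights=weights, H=payload["rounds"])


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Exhaustive weighted-error stump search.

    Returns (stump, weighted_error).  Candidate thresholds per feature are
    midpoints of consecutive sorted unique values; constant features are
    skipped.  Tie-break order: feature index, then threshold, then
    polarity +1 before -1.
    """
    best_err = np.inf
    best = None
    for j in range(X.shape[1]):
        uniq = np.unique(X[:, j])
        if uniq.size < 2:
            continue
        thr = 0.5 * (uniq[:-1] + uniq[1:])
        ge = X[:, j][:, None] >= thr[None, :]          # pred +1 region, polarity +1
        pred_pos = np.where(ge, 1, -1)
        err_pos = w @ (pred_pos != y[:, None])
        le = X[:, j][:, None] <= thr[None, :]          # polarity -1: sign(thr - x)
        pred_neg = np.where(le, 1, -1)
        err_neg = w @ (pred_neg != y[:, None])
        # interleave so that, per threshold, polarity +1 is examined first
        errs = np.empty(2 * thr.size)
        errs[0::2] = err_pos
        errs[1::2] = err_neg
        k = int(np.argmin(errs))
        if errs[k] < best_err - 1e-15:
            best_err = float(errs[k])
            best = WeakHypothesis(j, float(thr[k // 2]), 1 if k % 2 == 0 else -1)
    if best is None:
        raise DegenerateDataError("all features constant; no stump can split")
    return best, best_err


def train_adaboost(
    X, labels=None, H: int = 100, seed: Optional[int] = None
) -> EnsembleModel:
    """Train a discrete AdaBoost stump ensemble.

    ``X`` may be a labeled :class:`FeatureMatrix` or an (n, p) array with
    ``labels`` given separately.  ``seed`` is accepted for interface
    symmetry; the exhaustive stump search is deterministic.
    """
    if isinstance(X, FeatureMatrix):
        if X.labels is None:
            raise BadInputError("feature matrix carries no labels")
        labels = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if H < 1:
        raise BadInputError(f"need at least one round, got H={H}")
    if X.shape[0] != y.shape[0]:
        raise BadInputError("features and labels disagree")
    if np.unique(y).size < 2:
        raise DegenerateDataError("training set contains a single class")

    n = y.size
    w = np.full(n, 1.0 / n)
    stumps, rhos = [], []
    for _ in range(H):
        stump, err = _best_stump(X, y, w)
        if err >= 0.5:
            break
        rho = 0.5 * np.log((1.0 - max(err, _PERFECT_ERR)) / max(err, _PERFECT_ERR))
        stumps.append(stump)
        rhos.append(rho)
        if err <= _PERFECT_ERR:
            break
        pred = stump.predict(X)
        w = w * np.exp(-rho * y * pred)
        w /= w.sum()
    return EnsembleModel(hypotheses=stumps, weights=np.array(rhos), H=H)


def predict(model: EnsembleModel, X) -> np.ndarray:
    """Ensemble labels for an (n, p) array or FeatureMatrix."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    return model.predict(np.asarray(X, dtype=float))


# -- metrics ----------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Confusion counts and derived rates.

    The positive class for sensitivity is the clinically abnormal label
    (-1); specificity is computed on the clinically normal class (+1).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def evaluate(predicted, truth) -> Metrics:
    """Confusion-count metrics with abnormal (-1) as the positive class."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise BadInputError("prediction and truth lengths disagree")
    if predicted.size == 0:
        raise BadInputError("empty label sequences")
    pos, neg = -1, 1
    tp = int(np.sum((truth == pos) & (predicted == pos)))
    fn = int(np.sum((truth == pos) & (predicted == neg)))
    tn = int(np.sum((truth == neg) & (predicted == neg)))
    fp = int(np.sum((truth == neg) & (predicted == pos)))
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn)


# -- cross-validation -------------------------------------------------------

@dataclass
class CVResult:
    fold_metrics: list
    fold_assignment: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.fold_metrics]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([m.sensitivity for m in self.fold_metrics]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([m.specificity for m in self.fold_metrics]))

    def as_dict(self) -> dict:
        return {
            "folds": [m.as_dict() for m in self.fold_metrics],
            "mean": {
                "accuracy": self.mean_accuracy,
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity,
            },
        }


def stratified_kfold_cv(
    X, labels=None, K: int = 5, H: int = 100, seed: int = 0
) -> CVResult:
    """Stratified K-fold cross-validation of the stump ensemble.

    Within each class, examples are shuffled by a seeded generator and
    dealt round-robin into K folds, so fold class proportions match the
    data within one member.  Mean metrics are unweighted fold averages.
    """
    if isinstance(X, FeatureMatrix):
        if X.labels is None:
            raise BadInputError("feature matrix carries no labels")
        labels = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    fold = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < K:
            raise DegenerateDataError(
                f"class {cls:+d} has {idx.size} members, fewer than K={K}"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % K
    fold_metrics = []
    for k in range(K):
        test = fold == k
        model = train_adaboost(X[~test], y[~test], H=H)
        fold_metrics.append(evaluate(model.predict(X[test]), y[test]))
    return CVResult(fold_metrics=fold_metrics, fold_assignment=fold)


# -- statsmodels-style surface ---------------------------------------------

class HeartSoundBooster:
    """AdaBoost stump-ensemble model over a PCG feature matrix.

    Parameters
    ----------
    features : FeatureMatrix or (n, p) array
    labels : array of +1/-1, optional when ``features`` carries labels
    """

    def __init__(self, features, labels=None):
        if isinstance(features, FeatureMatrix):
            if features.labels is None and labels is None:
                raise BadInputError("no labels supplied")
            self.feature_names = list(features.feature_names)
            labels = features.labels if labels is None else labels
            features = features.values
        else:
            features = np.asarray(features, dtype=float)
            self.feature_names = [f"x{j}" for j in range(features.shape[1])]
        self.exog = features
        self.endog = np.asarray(labels, dtype=int)

    @classmethod
    def from_dataset(cls, dataset) -> "HeartSoundBooster":
        from .features import extract_matrix

        return cls(extract_matrix(dataset))

    def fit(self, rounds: int = 100, seed: Optional[int] = None) -> "BoosterResults":
        model = train_adaboost(self.exog, self.endog, H=rounds, seed=seed)
        return BoosterResults(self, model)

    def cross_validate(self, K: int = 5, rounds: int = 100, seed: int = 0) -> CVResult:
        return stratified_kfold_cv(self.exog, self.endog, K=K, H=rounds, seed=seed)


class BoosterResults:
    """Fitted ensemble with diagnostics.

    Attributes
    ----------
    ensemble : EnsembleModel
    train_metrics : Metrics on the training data
    """

    def __init__(self, model: HeartSoundBooster, ensemble: EnsembleModel):
        self.model = model
        self.ensemble = ensemble
        self.train_metrics = evaluate(
            ensemble.predict(model.exog), model.endog
        )

    def predict(self, X) -> np.ndarray:
        return predict(self.ensemble, X)

    def margin(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        return self.ensemble.margin(np.asarray(X, dtype=float))

    @property
    def stump_table(self) -> pd.DataFrame:
        names = self.model.feature_names
        return pd.DataFrame(
            {
                "round": np.arange(1, len(self.ensemble.hypotheses) + 1),
                "feature": [names[h.feature_index] for h in self.ensemble.hypotheses],
                "threshold": [h.threshold for h in self.ensemble.hypotheses],
                "polarity": [h.polarity for h in self.ensemble.hypotheses],
                "weight": self.ensemble.weights,
            }
        )

    def summary(self) -> str:
        m = self.train_metrics
        lines = [
            "Heart-sound AdaBoost ensemble",
            "=" * 46,
            f"training examples:     {self.model.endog.size}",
            f"rounds requested:      {self.ensemble.H}",
            f"stumps retained:       {len(self.ensemble.hypotheses)}",
            f"training accuracy:     {m.accuracy:.3f}",
            f"training sensitivity:  {m.sensitivity:.3f}",
            f"training specificity:  {m.specificity:.3f}",
            "",
            self.stump_table.head(10).to_string(index=False),
        ]
        if len(self.ensemble.hypotheses) > 10:
            lines.append(f"... {len(self.ensemble.hypotheses) - 10} more stumps")
        return "\n".join(lines)
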