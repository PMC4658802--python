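"""Linear SVM trained from scratch by stochastic gradient descent.

The objective is the L2-regularized hinge loss

    L(w, b) = (1/n) sum_i max(0, 1 - y_i (w.x_i + b)) + (lambda/2) ||w||^2

with the intercept excluded from the penalty.  Scores are mapped to
probabilities with the raw (uncalibrated) logistic of the margin,
p(y=+1 | x) = 1 / (1 + exp(-(w.x + b))), thresholded at 0.5.

Optimization is plain per-sample SGD with the standard strongly-convex
schedule eta_t = 1 / (lambda * (t + t0)), shuffling every epoch; training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

DEFAULT_LAMBDA = 0.001


def hinge_objective(w, b, X, y, lam: float = DEFAULT_LAMBDA) -> float:
    """Exact value of the regularized hinge objective."""
    w = np.asarray(w, dtype=float)
    margins = y * (X @ w + b)
    return float(np.mean(np.maximum(0.0, 1.0 - margins))
                 + 0.5 * lam * np.dot(w, w))


def hinge_subgradient(w, b, X, y, lam: float = DEFAULT_LAMBDA):
    """A subgradient of the objective at (w, b) (active where margin < 1)."""
    w = np.asarray(w, dtype=float)
    active = y * (X @ w + b) < 1.0
    n = len(y)
    gw = lam * w - (X[active].T @ y[active]) / n
    gb = -np.sum(y[active]) / n
    return gw, gb


class HingeSVC(BaseEstimator, ClassifierMixin):
    """Linear SVM with hinge loss, L2 penalty and SGD training.

    Parameters
    ----------
    lam : float
        Regularization strength (default 0.001).
    epochs : int
        Full passes over the shuffled training set.
    t0 : float or None
        Schedule offset; ``None`` uses 1/lam, which caps the first step at
        eta_1 ~ 1/(1 + lambda).
    seed : int
        Seed for the per-epoch shuffles.
    """

    def __init__(self, lam: float = DEFAULT_LAMBDA, epochs: int = 50,
                 t0: float | None = None, seed: int = 0, average: bool = True):
        self.lam = lam
        self.epochs = epochs
        self.t0 = t0
        self.seed = seed
        self.average = average

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if not np.all(np.isin(classes, (-1.0, 1.0))):
            raise ValueError("labels must be in {-1, +1}")
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        w = np.zeros(d)
        b = 0.0
        t0 = self.t0 if self.t0 is not None else 1.0 / self.lam
        t = 0
        # Polyak-Ruppert tail averaging over the last half of the epochs
        # smooths the SGD oscillation around the optimum
        avg_from = (self.epochs // 2) * n if self.average else self.epochs * n
        w_sum = np.zeros(d)
        b_sum = 0.0
        n_avg = 0
        for _ in range(self.epochs):
            for i in rng.permutation(n):
                t += 1
                eta = 1.0 / (self.lam * (t + t0))
                if y[i] * (X[i] @ w + b) < 1.0:
                    w *= 1.0 - eta * self.lam
                    w += eta * y[i] * X[i]
                    b += eta * y[i]
                else:
                    w *= 1.0 - eta * self.lam
                if t > avg_from:
                    w_sum += w
                    b_sum += b
                    n_avg += 1
        if n_avg:
            w = w_sum / n_avg
            b = b_sum / n_avg
        self.coef_ = w
        self.intercept_ = float(b)
        self.classes_ = np.array([-1.0, 1.0])
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        from scipy.special import expit

        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return np.where(self.predict_proba(X)[:, 1] >= 0.5, 1.0, -1.0)

    def objective(self, X, y) -> float:
        return hinge_objective(self.coef_, self.intercept_,
                               np.asarray(X, dtype=float),
                               np.asarray(y, dtype=float), self.lam)


def train(X, y, lam: float = DEFAULT_LAMBDA, epochs: int = 50,
          t0: float | None = None, seed: int = 0) -> HingeSVC:
    """Functional wrapper around :class:`HingeSVC`."""
    return HingeSVC(lam=lam, epochs=epochs, t0=t0, seed=seed).fit(X, y)


# model persistence ----------------------------------------------------------

def model_to_json(clf: HingeSVC, columns, mean, scale) -> str:
    """Serialize a fitted model plus its standardization parameters."""
    return json.dumps({
        "format": "mircurve-linear-model/1",
        "lambda": clf.lam,
        "epochs": clf.epochs,
        "seed": clf.seed,
        "columns": list(columns),
        "mean": list(map(float, mean)),
        "scale": list(map(float, scale)),
        "w": list(map(float, clf.coef_)),
        "b": clf.intercept_,
    }, indent=1)


def model_from_json(text: str):
    """Inverse of :func:`model_to_json`; returns (clf, columns, mean, scale)."""
    obj = json.loads(text)
    if obj.get("format") != "mircurve-linear-model/1":
        raise ValueError("unrecognized model file format")
    clf = HingeSVC(lam=obj["lambda"], epochs=obj["epochs"], seed=obj["seed"])
    clf.coef_ = np.array(obj["w"], dtype=float)
    clf.intercept_ = float(obj["b"])
    clf.classes_ = np.array([-1.0, 1.0])
    clf.n_features_in_ = len(clf.coef_)
    return clf, obj["columns"], np.array(obj["mean"]), np.array(obj["scale"])
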