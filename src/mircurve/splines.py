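"""Cubic B-spline representation of the 27-point spatial profiles.

Each profile is projected onto K cubic B-spline basis functions evaluated at
t = 0..26 (a clamped, uniform knot vector), and the K least-squares
coefficients replace the raw vector as model covariates.  Coefficients solve
the normal equations c = (Psi^T Psi)^{-1} Psi^T f; a pseudo-inverse fallback
guards against (practically unreachable) rank deficiency.  One shared K is
used for all six curve features; it can be chosen by cross-validation
maximizing the TPR-FPR gap of the downstream classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, solve
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import PROFILE_LEN, W

DEGREE = 3
DEFAULT_K = 20
K_MIN, K_MAX = 4, PROFILE_LEN


def knot_count(K: int, degree: int = DEGREE) -> int:
    """Reported knot count of the least-squares spline fit: K - degree + 2."""
    return K - degree + 2


@dataclass
class BSplineBasis:
    """K cubic B-spline basis functions tabulated on t = 0..2W."""

    K: int
    degree: int = DEGREE
    knots: np.ndarray = field(init=False)
    Psi: np.ndarray = field(init=False)

    def __post_init__(self):
        if not (K_MIN <= self.K <= K_MAX):
            raise ValueError(f"K must be in [{K_MIN}, {K_MAX}], got {self.K}")
        hi = 2 * W
        interior = np.linspace(0.0, hi, self.K - self.degree + 1)[1:-1]
        self.knots = np.concatenate([
            np.full(self.degree + 1, 0.0), interior, np.full(self.degree + 1, hi)])
        t = np.arange(PROFILE_LEN, dtype=float)
        self.Psi = BSpline.design_matrix(t, self.knots, self.degree,
                                         extrapolate=False).toarray()

    @property
    def n_knots(self) -> int:
        return knot_count(self.K, self.degree)


def build_basis(K: int, degree: int = DEGREE) -> BSplineBasis:
    """Uniform clamped cubic B-spline basis with K functions on t = 0..26."""
    return BSplineBasis(K=K, degree=degree)


def fit_curve(values, basis: BSplineBasis) -> np.ndarray:
    """Least-squares B-spline coefficients of one (or many) profiles.

    ``values`` may be a length-27 vector or an (n, 27) matrix; missing
    values must already be zeroed.  Solves the normal equations; falls back
    to the pseudo-inverse with a warning if Psi^T Psi is singular.
    """
    f = np.atleast_2d(np.asarray(values, dtype=float))
    if f.shape[1] != PROFILE_LEN:
        raise ValueError(f"profiles must have length {PROFILE_LEN}")
    Psi = basis.Psi
    PtP = Psi.T @ Psi
    Ptf = Psi.T @ f.T
    try:
        c = solve(PtP, Ptf, assume_a="pos")
    except LinAlgError:
        warnings.warn("normal equations singular; using pseudo-inverse")
        c = np.linalg.pinv(PtP) @ Ptf
    c = c.T
    return c[0] if np.ndim(values) == 1 else c


class BSplineFeaturizer(BaseEstimator, TransformerMixin):
    """Transform (n, 27) profile matrices into (n, K) spline coefficients."""

    def __init__(self, n_basis: int = DEFAULT_K):
        self.n_basis = n_basis

    def fit(self, X, y=None):
        self.basis_ = build_basis(self.n_basis)
        return self

    def transform(self, X):
        return fit_curve(np.asarray(X, dtype=float), self.basis_)

    def reconstruct(self, coefficients):
        """Evaluate the fitted curves back on the 27 sample points."""
        return np.asarray(coefficients) @ self.basis_.Psi.T


def select_K(dataset, candidate_Ks, cv_folds: int = 10, seed: int = 0,
             lam: float = 0.001, epochs: int = 50):
    """Choose the shared basis size by cross-validation.

    For each candidate K the downstream site classifier is cross-validated
    on ``dataset`` (a :class:`~mircurve.features.SiteDataset`) and the mean
    best TPR-FPR gap over held-out folds is recorded; the argmax wins, with
    ties going to the smaller K.
    """
    from .evaluate import cv_tpr_fpr_gap  # local import: avoids a cycle

    best_K, best_gap = None, -np.inf
    for K in sorted(candidate_Ks):
        if not (K_MIN <= K <= K_MAX):
            raise ValueError(f"candidate K {K} outside [{K_MIN}, {K_MAX}]")
        gap = cv_tpr_fpr_gap(dataset, n_basis=K, folds=cv_folds, seed=seed,
                             lam=lam, epochs=epochs)
        if gap > best_gap + 1e-12:
            best_K, best_gap = K, gap
    return best_K
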