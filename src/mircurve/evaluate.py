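"""Validation protocol: negative subsampling, k-fold CV, averaged ROC.

Class balance is restored per run by keeping every positive and drawing an
equal-size negative subsample without replacement.  Each run is split into
stratified folds; the site classifier (including its enrichment table and
standardization) is refit on each training split and scored on the held-out
fold.  True- and false-positive rates are computed on a fixed probability
threshold grid and averaged pointwise across all runs x folds, giving one
mean ROC curve (with the best operating point at max TPR - FPR).  A
cross-species mode trains on one dataset and scores another, and a
stratified report breaks the shared scores down by region x seed/seedless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import SiteDataset, TargetSiteClassifier


def _probability_grid():
    """Fixed probability-threshold grid, logit-spaced.

    The uncalibrated logistic saturates for confidently scored sites, so a
    uniform grid on [0, 1] cannot separate them; spacing thresholds evenly
    on the logit scale keeps resolution in both tails.
    """
    from scipy.special import expit

    t = np.concatenate([[1.0], expit(np.linspace(30.0, -30.0, 401)), [0.0]])
    return np.unique(t)[::-1]


THRESHOLD_GRID = _probability_grid()  # descending sweep


@dataclass
class RocCurve:
    """An ROC curve over the threshold sweep, plus its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    tpr_sd: np.ndarray | None = field(default=None, repr=False)

    @property
    def best_operating_point(self) -> tuple[float, float]:
        """(FPR, TPR) where TPR - FPR is maximal (Youden point)."""
        k = int(np.argmax(self.tpr - self.fpr))
        return float(self.fpr[k]), float(self.tpr[k])


def roc_points(scores, y, thresholds=THRESHOLD_GRID):
    """(FPR, TPR) at each threshold; a site is called + when score >= t."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        called = scores >= t
        tpr[k] = (called & pos).sum() / n_pos if n_pos else np.nan
        fpr[k] = (called & ~pos).sum() / n_neg if n_neg else np.nan
    return fpr, tpr


def trapezoid_auc(fpr, tpr) -> float:
    """Area under a curve given as threshold-ordered (FPR, TPR) points."""
    f = np.concatenate([[0.0], np.asarray(fpr), [1.0]])
    t = np.concatenate([[0.0], np.asarray(tpr), [1.0]])
    order = np.argsort(f, kind="stable")
    return float(np.trapezoid(t[order], f[order]))


def roc_from_scores(scores, y, thresholds=THRESHOLD_GRID) -> RocCurve:
    fpr, tpr = roc_points(scores, y, thresholds)
    pos = np.asarray(y) > 0
    return RocCurve(fpr=fpr, tpr=tpr, auc=trapezoid_auc(fpr, tpr),
                    n_pos=int(pos.sum()), n_neg=int((~pos).sum()))


def subsample_balance(y, rng) -> np.ndarray:
    """Indices of all positives plus an equal negative subsample.

    Falls back (with a warning) to keeping every negative when negatives
    are scarcer than positives.
    """
    y = np.asarray(y)
    pos_idx = np.flatnonzero(y > 0)
    neg_idx = np.flatnonzero(y <= 0)
    if len(neg_idx) < len(pos_idx):
        warnings.warn("fewer negatives than positives; keeping all negatives")
        chosen = neg_idx
    else:
        chosen = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    return np.sort(np.concatenate([pos_idx, chosen]))


def stratified_folds(y, folds: int, rng) -> list[np.ndarray]:
    """Deal shuffled positives and negatives round-robin into k folds."""
    y = np.asarray(y)
    assignments = [[] for _ in range(folds)]
    for mask in (y > 0, y <= 0):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            assignments[k % folds].append(i)
    return [np.sort(np.array(a, dtype=int)) for a in assignments]


def _mean_roc(curves: list[tuple[np.ndarray, np.ndarray]],
              n_pos: int, n_neg: int) -> RocCurve:
    fprs = np.stack([c[0] for c in curves])
    tprs = np.stack([c[1] for c in curves])
    fpr, tpr = fprs.mean(axis=0), tprs.mean(axis=0)
    return RocCurve(fpr=fpr, tpr=tpr, auc=trapezoid_auc(fpr, tpr),
                    n_pos=n_pos, n_neg=n_neg, tpr_sd=tprs.std(axis=0))


def _clf_factory(seed: int, **params) -> TargetSiteClassifier:
    return TargetSiteClassifier(seed=seed, **params)


def cross_validate(dataset: SiteDataset, folds: int = 10,
                   subsample_runs: int = 10, seed: int = 0,
                   **clf_params) -> RocCurve:
    """Mean ROC over ``subsample_runs`` balanced subsamples x k-fold CV.

    Every training split refits the full classifier (enrichment table,
    standardization, SVM); every held-out fold contributes one
    threshold-grid (FPR, TPR) curve, and all runs x folds curves are
    averaged pointwise.
    """
    master = np.random.SeedSequence(seed)
    run_seeds = master.spawn(subsample_runs)
    curves = []
    tot_pos = tot_neg = 0
    for r in range(subsample_runs):
        rng = np.random.default_rng(run_seeds[r])
        sub_idx = subsample_balance(dataset.y, rng)
        sub = dataset.subset(sub_idx)
        for attempt in range(10):
            fold_idx = stratified_folds(sub.y, folds, rng)
            ok_train = all(len(np.unique(np.delete(sub.y, f))) == 2
                           for f in fold_idx)
            ok_test = all(len(np.unique(sub.y[f])) == 2 for f in fold_idx)
            if ok_train and ok_test:
                break
            warnings.warn("degenerate fold (single-class split); reshuffling")
        for f, test_idx in enumerate(fold_idx):
            train_idx = np.setdiff1d(np.arange(len(sub)), test_idx)
            clf = _clf_factory(seed=int(rng.integers(2 ** 31)), **clf_params)
            clf.fit(sub.subset(train_idx))
            scores = clf.predict_proba(sub.subset(test_idx))[:, 1]
            y_test = sub.y[test_idx]
            curves.append(roc_points(scores, y_test))
            tot_pos += int((y_test > 0).sum())
            tot_neg += int((y_test <= 0).sum())
    return _mean_roc(curves, tot_pos, tot_neg)


def cross_species(train_set: SiteDataset, test_set: SiteDataset,
                  subsample_runs: int = 10, seed: int = 0,
                  **clf_params) -> RocCurve:
    """Train on balanced subsamples of one dataset, score the other."""
    if list(train_set.curves) != list(test_set.curves):
        raise ValueError("feature schema mismatch between datasets")
    master = np.random.SeedSequence(seed)
    run_seeds = master.spawn(subsample_runs)
    curves = []
    tot_pos = tot_neg = 0
    for r in range(subsample_runs):
        rng = np.random.default_rng(run_seeds[r])
        train = train_set.subset(subsample_balance(train_set.y, rng))
        test = test_set.subset(subsample_balance(test_set.y, rng))
        clf = _clf_factory(seed=int(rng.integers(2 ** 31)), **clf_params)
        clf.fit(train)
        scores = clf.predict_proba(test)[:, 1]
        curves.append(roc_points(scores, test.y))
        tot_pos += int((test.y > 0).sum())
        tot_neg += int((test.y <= 0).sum())
    return _mean_roc(curves, tot_pos, tot_neg)


def stratified_report(scores, dataset: SiteDataset) -> dict[str, RocCurve | None]:
    """Per-stratum ROC from shared scores; strata are region x seed flag.

    A stratum missing either class maps to ``None`` (undefined sentinel).
    """
    scores = np.asarray(scores, dtype=float)
    meta = dataset.meta
    out: dict[str, RocCurve | None] = {}
    flags = np.where(meta["seed"].to_numpy(), "seed", "seedless")
    for region in sorted(meta["region"].unique()):
        for flag in ("seed", "seedless"):
            mask = (meta["region"] == region).to_numpy() & (flags == flag)
            if not mask.any():
                continue
            y = dataset.y[mask]
            key = f"{region}/{flag}"
            if len(np.unique(y)) < 2:
                out[key] = None
            else:
                out[key] = roc_from_scores(scores[mask], y)
    out["all"] = roc_from_scores(scores, dataset.y)
    return out


def normalized_candidate_set_size(n_candidates: int, n_mirna: int,
                                  n_mrna: int) -> float:
    """Candidate count divided by (#miRNA x #mRNA)."""
    if n_mirna <= 0 or n_mrna <= 0:
        raise ValueError("denominators must be positive")
    return n_candidates / (n_mirna * n_mrna)


def cv_tpr_fpr_gap(dataset: SiteDataset, n_basis: int, folds: int = 10,
                   seed: int = 0, lam: float = 0.001, epochs: int = 50) -> float:
    """Mean best TPR-FPR gap over held-out folds (used for K selection)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sub = dataset.subset(subsample_balance(dataset.y, rng))
    gaps = []
    fold_idx = stratified_folds(sub.y, folds, rng)
    for test_idx in fold_idx:
        train_idx = np.setdiff1d(np.arange(len(sub)), test_idx)
        clf = TargetSiteClassifier(n_basis=n_basis, lam=lam, epochs=epochs,
                                   seed=int(rng.integers(2 ** 31)))
        clf.fit(sub.subset(train_idx))
        scores = clf.predict_proba(sub.subset(test_idx))[:, 1]
        fpr, tpr = roc_points(scores, sub.y[test_idx])
        gaps.append(float(np.nanmax(tpr - fpr)))
    return float(np.mean(gaps))
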