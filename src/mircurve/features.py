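"""Per-site feature assembly and the end-to-end site classifier.

A candidate site contributes six 27-point spatial profiles plus scalar
covariates: seed-pattern enrichment, three conservation summaries, site
length, the genic region holding the site and the site's relative location
within that region.  The design matrix has dimension 6K + 8 for basis size
K: six K-coefficient curve blocks, then
``seed_enrichment, site_consv, seed_consv, offseed_consv, site_length,
region_cds, region_five_utr, relative_location`` (3' UTR is the region
baseline, so two dummy columns encode the three regions).

:class:`TargetSiteClassifier` bundles everything that must be learned from
training folds only — the pattern-enrichment table, the spline bases, the
column standardization and the SVM weights — behind one sklearn-style
fit/predict surface, which keeps the cross-validation protocol free of label
leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .duplex import best_seed_region
from .energy import EnergyModel
from .enrichment import build_pattern_table, enrichment_of
from .profiles import (DEFAULT_FOLD_CONTEXT, PROFILE_FEATURES, PROFILE_LEN,
                       site_profiles)
from .splines import DEFAULT_K, BSplineFeaturizer
from .svm import DEFAULT_LAMBDA, HingeSVC

REGIONS_ORDERED = ("three_utr", "cds", "five_utr")
SCALAR_COLUMNS = ("seed_enrichment", "site_consv", "seed_consv",
                  "offseed_consv", "site_length", "region_cds",
                  "region_five_utr", "relative_location")


def conservation_features(site, transcript, seed_region=None):
    """(site, seed, off-seed) mean conservation for one site.

    Seed and off-seed means apply only to canonical seed sites; seedless
    sites report 0 for both.
    """
    cons = transcript.conservation
    site_mean = float(np.mean(cons[site.start:site.end])) if site.end > site.start else 0.0
    if not site.seed:
        return site_mean, 0.0, 0.0
    s, e = seed_region if seed_region is not None else site.seed_region
    seed_mean = float(np.mean(cons[s:e])) if e > s else 0.0
    off_idx = [i for i in range(site.start, site.end) if not s <= i < e]
    off_mean = float(np.mean(cons[off_idx])) if off_idx else 0.0
    return site_mean, seed_mean, off_mean


def locate_site(site, regions):
    """(region name, relative location in [0, 1]) of the site's 5' end.

    The region of the 5'-most site nucleotide decides; 0 marks the region's
    5' end and 1 its 3' end.
    """
    for name in REGIONS_ORDERED:
        if name not in regions:
            continue
        start, end = regions[name]
        if start <= site.start < end:
            denom = end - start - 1
            rel = 0.0 if denom <= 0 else (site.start - start) / denom
            return name, float(min(1.0, max(0.0, rel)))
    raise ValueError(
        f"site start {site.start} outside all annotated regions "
        f"of {site.transcript_id}")


@dataclass
class SiteDataset:
    """Assembled per-site ingredients: metadata table + profile matrices.

    ``meta`` has one row per site (ids, coordinates, seed flag, dash-joined
    pattern, region, scalar covariates, label); ``curves`` maps each profile
    feature to an (n_sites, 27) matrix with masked windows already zeroed.
    """

    meta: pd.DataFrame
    curves: dict[str, np.ndarray]

    def __len__(self):
        return len(self.meta)

    @property
    def y(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=float)

    def subset(self, indices) -> "SiteDataset":
        indices = np.asarray(indices)
        return SiteDataset(
            meta=self.meta.iloc[indices].reset_index(drop=True),
            curves={k: v[indices] for k, v in self.curves.items()})

    def patterns(self) -> list[tuple[int, ...]]:
        return [tuple(int(c) for c in p.split("-"))
                for p in self.meta["pattern"]]


def build_site_dataset(sites, transcripts, mirnas,
                       model: EnergyModel | None = None,
                       fold_context: int = DEFAULT_FOLD_CONTEXT) -> SiteDataset:
    """Compute profiles and scalar covariates for labeled candidate sites.

    Seedless sites get their seed-resolution center re-pinned to the best
    guide-1-8 hybridization window inside the site before profiling.
    Transcripts without full region annotation raise (the annotation must
    tile the transcript).
    """
    model = model or EnergyModel.default()
    tx_by_id = {t.id: t for t in transcripts}
    mir_by_id = {m.id: m for m in mirnas}
    curves = {f: np.zeros((len(sites), PROFILE_LEN)) for f in PROFILE_FEATURES}
    meta_rows = []
    for k, site in enumerate(sites):
        tx = tx_by_id[site.transcript_id]
        mir = mir_by_id[site.mirna_id]
        if not site.seed:
            site.seed_region = best_seed_region((site.start, site.end), tx,
                                                mir, model)
        profs = site_profiles(site, tx, mir, model, fold_context)
        for f in PROFILE_FEATURES:
            curves[f][k] = profs[f].values
        site_c, seed_c, off_c = conservation_features(site, tx)
        region, rel = locate_site(site, tx.regions)
        meta_rows.append({
            "mirna_id": site.mirna_id, "transcript_id": site.transcript_id,
            "start": site.start, "end": site.end, "seed": bool(site.seed),
            "delta_g": site.delta_g,
            "pattern": "-".join(map(str, site.pattern)),
            "region": region, "relative_location": rel,
            "site_length": site.end - site.start,
            "site_consv": site_c, "seed_consv": seed_c, "offseed_consv": off_c,
            "label": int(site.label),
        })
    return SiteDataset(meta=pd.DataFrame(meta_rows), curves=curves)


def feature_columns(n_basis: int = DEFAULT_K) -> list[str]:
    """Canonical design-matrix column names for basis size K."""
    cols = [f"{f}[{k}]" for f in PROFILE_FEATURES for k in range(n_basis)]
    return cols + list(SCALAR_COLUMNS)


class TargetSiteClassifier(BaseEstimator, ClassifierMixin):
    """Spline features + enrichment + standardization + linear SVM.

    Fit on a :class:`SiteDataset`; every learned ingredient (the pattern
    enrichment table, the per-column mean/scale, the SVM weights) comes from
    the training data only.

    Parameters
    ----------
    n_basis : int
        Shared B-spline basis size K for all six curves (default 20).
    lam : float
        SVM regularization strength (default 0.001).
    enrichment_tail : bool
        Score patterns with the upper-tail probability instead of the
        probability mass (default False, the as-printed definition).
    """

    def __init__(self, n_basis: int = DEFAULT_K, lam: float = DEFAULT_LAMBDA,
                 epochs: int = 50, enrichment_tail: bool = False, seed: int = 0):
        self.n_basis = n_basis
        self.lam = lam
        self.epochs = epochs
        self.enrichment_tail = enrichment_tail
        self.seed = seed

    # -- design matrix ---------------------------------------------------
    def _raw_matrix(self, dataset: SiteDataset) -> np.ndarray:
        blocks = [self.featurizer_.transform(dataset.curves[f])
                  for f in PROFILE_FEATURES]
        meta = dataset.meta
        enrich = np.array([enrichment_of(p, self.pattern_table_)
                           for p in dataset.patterns()])
        scalars = np.column_stack([
            enrich,
            meta["site_consv"].to_numpy(dtype=float),
            meta["seed_consv"].to_numpy(dtype=float),
            meta["offseed_consv"].to_numpy(dtype=float),
            meta["site_length"].to_numpy(dtype=float),
            (meta["region"] == "cds").to_numpy(dtype=float),
            (meta["region"] == "five_utr").to_numpy(dtype=float),
            meta["relative_location"].to_numpy(dtype=float),
        ])
        return np.hstack(blocks + [scalars])

    def transform(self, dataset: SiteDataset) -> np.ndarray:
        """Standardized design matrix under the fitted parameters."""
        return (self._raw_matrix(dataset) - self.mean_) / self.scale_

    # -- estimator surface ----------------------------------------------
    def fit(self, dataset: SiteDataset, y=None):
        y = dataset.y if y is None else np.asarray(y, dtype=float)
        positives = [p for p, lab in zip(dataset.patterns(), y) if lab > 0]
        self.pattern_table_ = build_pattern_table(positives,
                                                  tail=self.enrichment_tail)
        self.featurizer_ = BSplineFeaturizer(n_basis=self.n_basis).fit(None)
        X = self._raw_matrix(dataset)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0.0] = 1.0
        self.columns_ = feature_columns(self.n_basis)
        self.svc_ = HingeSVC(lam=self.lam, epochs=self.epochs, seed=self.seed)
        self.svc_.fit((X - self.mean_) / self.scale_, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, dataset: SiteDataset) -> np.ndarray:
        return self.svc_.decision_function(self.transform(dataset))

    def predict_proba(self, dataset: SiteDataset) -> np.ndarray:
        return self.svc_.predict_proba(self.transform(dataset))

    def predict(self, dataset: SiteDataset) -> np.ndarray:
        return self.svc_.predict(self.transform(dataset))
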