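"""End-to-end convenience wrappers: fixture -> candidates -> features -> CV."""

from __future__ import annotations

from .duplex import generate_candidates, label_sites
from .energy import EnergyModel
from .evaluate import RocCurve, cross_validate
from .features import SiteDataset, build_site_dataset
from .profiles import DEFAULT_FOLD_CONTEXT
from .simulate import Fixture, FixtureSpec, generate


def labeled_candidates(fixture: Fixture, model: EnergyModel | None = None,
                       dg_threshold: float = -15.0):
    """Candidate sites for a fixture, labeled by CLIP containment."""
    model = model or EnergyModel.default()
    sites = generate_candidates(fixture.mirnas, fixture.transcripts, model,
                                dg_threshold=dg_threshold)
    return label_sites(sites, fixture.clip_regions)


def dataset_from_fixture(fixture: Fixture, model: EnergyModel | None = None,
                         dg_threshold: float = -15.0,
                         fold_context: int = DEFAULT_FOLD_CONTEXT) -> SiteDataset:
    """Assembled site dataset (profiles + scalars + labels) for a fixture."""
    model = model or EnergyModel.default()
    sites = labeled_candidates(fixture, model, dg_threshold)
    return build_site_dataset(sites, fixture.transcripts, fixture.mirnas,
                              model, fold_context)


def run_pipeline(spec: FixtureSpec, folds: int = 10, subsample_runs: int = 10,
                 seed: int = 0, n_basis: int = 20, lam: float = 0.001,
                 model: EnergyModel | None = None) -> tuple[SiteDataset, RocCurve]:
    """simulate -> candidates -> features -> subsampled-CV ROC."""
    fixture = generate(spec, model)
    dataset = dataset_from_fixture(fixture, model)
    roc = cross_validate(dataset, folds=folds, subsample_runs=subsample_runs,
                         seed=seed, n_basis=n_basis, lam=lam)
    return dataset, roc
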