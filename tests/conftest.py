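import numpy as np
import pytest

from mircurve.energy import EnergyModel


@pytest.fixture(scope="session")
def model():
    return EnergyModel.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


def make_synthetic_dataset(n=160, seed=0, signal=1.5, scalar_signal=0.0):
    """A SiteDataset with direct control over label-feature association.

    ``signal`` shifts the au_site curve by a smooth arch times the label;
    ``scalar_signal`` shifts site_consv by the label.  Zero for both gives a
    label-independent (null) dataset.
    """
    import pandas as pd

    from mircurve.features import SiteDataset
    from mircurve.profiles import PROFILE_FEATURES

    rng_ = np.random.default_rng(seed)
    t = np.arange(27.0)
    shape = np.sin(t / 26 * np.pi)
    y = rng_.choice([-1, 1], size=n)
    curves = {}
    for f in PROFILE_FEATURES:
        base = rng_.normal(size=(n, 27))
        if f == "au_site" and signal:
            base += np.outer(y, shape) * signal
        curves[f] = base
    meta = pd.DataFrame({
        "mirna_id": "m", "transcript_id": "t",
        "start": np.arange(n), "end": np.arange(n) + 20,
        "seed": rng_.random(n) < 0.5, "delta_g": -20.0,
        "pattern": ["1-1-1-1-1-1-1-1"] * n,
        "region": rng_.choice(["three_utr", "cds", "five_utr"], size=n),
        "relative_location": rng_.random(n), "site_length": 20,
        "site_consv": np.clip(0.5 + scalar_signal * y
                              + 0.05 * rng_.normal(size=n), 0, 1),
        "seed_consv": 0.5, "offseed_consv": 0.5, "label": y,
    })
    return SiteDataset(meta=meta, curves=curves)
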