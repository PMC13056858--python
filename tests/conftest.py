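import warnings

import numpy as np
import pandas as pd
import pytest

from peptidiag.peaks import FeatureMatrix
from peptidiag.pipeline import spectra_to_features
from peptidiag.simulate import default_config, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*does not have valid feature names.*")


@pytest.fixture(scope="session")
def medium_cohort():
    """One 200 TC / 200 HC cohort at default study conditions, shared across
    tests that need realistic spectra."""
    cfg = default_config(seed=42, n_tc=200, n_hc=200)
    spectra, labels, truth = generate_cohort(cfg)
    return cfg, spectra, labels, truth


@pytest.fixture(scope="session")
def medium_features(medium_cohort):
    """Feature matrix derived from the shared cohort via the full spectral
    pipeline."""
    cfg, spectra, labels, truth = medium_cohort
    fm = spectra_to_features(spectra, labels, truth.artifact_mz)
    return cfg, fm, truth


def synthetic_matrix(
    n_per_class: int = 100,
    n_features: int = 30,
    effect_features=(0, 1),
    log2fc: float = 1.0,
    cv: float = 0.2,
    seed: int = 0,
) -> FeatureMatrix:
    """Tabular (non-spectral) two-class log-normal feature matrix for fast
    classifier/importance tests; features in ``effect_features`` carry the
    given fold change in TC."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + cv * cv))
    base = rng.uniform(50, 150, n_features)
    rows, labels = [], []
    for cls, fc_on in (("TC", True), ("HC", False)):
        for _ in range(n_per_class):
            mean = base.copy()
            if fc_on:
                mean[list(effect_features)] *= 2.0**log2fc
            mu = np.log(mean) - 0.5 * sigma**2
            rows.append(rng.lognormal(mu, sigma))
            labels.append(cls)
    ids = [f"S{i:04d}" for i in range(len(rows))]
    cols = [1000.0 + 50.0 * j for j in range(n_features)]
    values = pd.DataFrame(np.asarray(rows), index=ids, columns=cols)
    return FeatureMatrix(
        values=values,
        labels=pd.Series(labels, index=ids),
        fill_mask=pd.DataFrame(False, index=ids, columns=cols),
    )
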