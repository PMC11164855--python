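import numpy as np
import pandas as pd
import pytest

from fairsite.synthetic_cohort import GeneratorConfig, SiteSpec, generate_cohort


def make_table(X, y, sites=None, split=None, feature_names=None) -> pd.DataFrame:
    """Assemble a cohort table from raw arrays."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    table = pd.DataFrame(X, columns=feature_names)
    table["label"] = np.asarray(y, dtype=int)
    table["site"] = "site_A" if sites is None else np.asarray(sites)
    table["split"] = "unassigned" if split is None else split
    return table


@pytest.fixture
def separable_table() -> pd.DataFrame:
    """Linearly separable toy cohort: one informative feature, two sites."""
    rng = np.random.default_rng(7)
    n = 600
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 3))
    X[:, 0] += 6.0 * y  # wide margin
    sites = np.where(rng.random(n) < 0.5, "site_A", "site_B")
    return make_table(X, y, sites)


@pytest.fixture
def noise_table() -> pd.DataFrame:
    """Labels independent of all features."""
    rng = np.random.default_rng(11)
    n = 1500
    return make_table(rng.standard_normal((n, 4)), rng.integers(0, 2, n))


def two_site_config(shift=None, n=2000, prevalence=0.05, seed=0, n_features=4) -> GeneratorConfig:
    features = tuple(f"f{j}" for j in range(n_features))
    return GeneratorConfig(
        features=features,
        class_effect={},
        sites=(
            SiteSpec("site_A", n, prevalence),
            SiteSpec("site_E", n, prevalence, shift=shift or {}),
        ),
        seed=seed,
    )


@pytest.fixture
def shifted_pair() -> pd.DataFrame:
    """Two sites, one feature location-shifted by +2 SD at site_E."""
    return generate_cohort(two_site_config(shift={"f2": (2.0, 1.0)}))
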