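import numpy as np
import pytest

from mindcpm.synthetic import GeneratorConfig, SiteConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-site planted-signal cohort small enough for oracle checks."""
    cfg = GeneratorConfig(
        n_nodes=20,
        sites=(SiteConfig("siteA", 80, 134.8, 17.8),),
        n_planted_positive=8,
        n_planted_negative=8,
        effect_r=0.4,
        rng_seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_site_cohort():
    """Two sites sharing the planted effect, for external validation."""
    cfg = GeneratorConfig(
        n_nodes=40,
        sites=(
            SiteConfig("train", 150, 134.8, 17.8),
            SiteConfig("test", 100, 126.8, 17.4),
        ),
        n_planted_positive=15,
        n_planted_negative=15,
        effect_r=0.35,
        rng_seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def site_slice(cohort, name):
    idx = cohort.phenotype.index[cohort.phenotype["site"] == name].to_numpy()
    return cohort.edges[idx], cohort.phenotype.loc[idx]
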