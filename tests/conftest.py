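import numpy as np
import pytest

from fundusmap.pedigree import MutationSite, breed_pedigree, draw_mutation_set


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_sites():
    return [
        MutationSite("siteA", "1", 10_000_000, "geneA", "probably_damaging"),
        MutationSite("siteB", "7", 55_000_000, "geneB", "probably_benign"),
    ]


@pytest.fixture
def small_pedigree(two_sites, rng):
    return breed_pedigree(two_sites, n_g2_dams=2, n_g3_per_dam=3, rng=rng, seed=1)


@pytest.fixture
def screen_pedigree(rng):
    """Default screen-shaped pedigree: 60 sites, 5 dams x 8 pups."""
    sites = draw_mutation_set(60, rng=rng)
    return breed_pedigree(sites, n_g2_dams=5, n_g3_per_dam=8, rng=rng, seed=2)
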