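import numpy as np
import pytest

from cladescan.model_library import ModelLibrary
from cladescan.synthetic_fixtures import make_family, make_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family():
    """One 120-aa family with 2 clades, fixed seed (session-wide)."""
    g = np.random.default_rng(7)
    return make_family(g, length=120, n_seed=6, n_clades=2, domain_acc="SF00001")


@pytest.fixture(scope="session")
def small_library(small_family) -> ModelLibrary:
    return make_library([small_family])


@pytest.fixture(scope="session")
def trained_small(small_family, small_library):
    """Training set + fitted probability spaces for the small family."""
    from cladescan.bayes_space import fit_space
    from cladescan.training_set import build_training_set

    g = np.random.default_rng(11)
    scm, ccms = small_library.models_for_domain(small_family.domain_acc)
    instances = build_training_set(
        small_family.all_seed_rows(), scm, ccms, small_family.domain_acc, g, markov_budget=600
    )
    spaces = {}
    for mtype in ("SCM", "CCM"):
        sub = [t for t in instances if t.model_type == mtype]
        if sub:
            spaces[(small_family.domain_acc, mtype)] = fit_space(sub)
    return instances, spaces
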