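import numpy as np
import pytest
from hypothesis import settings

from cncnet.synthetic import SyntheticSpec, simulate_all

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


SMALL_SPEC = SyntheticSpec(
    n_mirna=12, n_lncrna=15, n_mrna=50,
    de_fraction_per_class=0.4, n_target_pairs=4,
    utr_length=150, n_genesets=8, geneset_size=10,
    rng_seed=2018,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated study shared across read-only tests."""
    return simulate_all(SMALL_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(20181029)
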