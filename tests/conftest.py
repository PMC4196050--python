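import numpy as np
import pytest
from hypothesis import settings

from onestepblend import SimConfig, simulate_population

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: reduced population used by most unit tests (156 animals, 66 genotyped)
SMALL = SimConfig(
    n_sires=6,
    n_ref_cows=60,
    n_val_cows=20,
    n_dams_nongeno=10,
    n_halfsibs_per_sire=5,
    n_snps=300,
    n_qtl=60,
    seed=11,
)


@pytest.fixture(scope="session")
def small_population():
    return simulate_population(SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140)
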