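import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from raretaxa.partition import classify_gsp, filter_low_count, rarefy
from raretaxa.simulate import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 samples x 300 OTUs, all structure planted, depth 20k."""
    return generate_dataset(
        n_samples=20, n_otus=300, depth=20_000, seed=3,
        frac_env_responsive=0.15, frac_module_members=0.2,
    )


@pytest.fixture(scope="session")
def processed(small_dataset):
    """Rarefied + low-count-filtered table with its GSP partition."""
    table, meta, env, truth = small_dataset
    t2 = filter_low_count(rarefy(table, seed=1), 20)
    return t2, classify_gsp(t2), meta, env, truth
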