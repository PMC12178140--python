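import numpy as np
import pytest

from rnagae import RNARecord, SyntheticSpec, build_graph, featurize, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset shared by training-level tests."""
    spec = SyntheticSpec(n_mirna=60, n_lncrna=60, seed=7)
    records, pairs, truth = generate(spec)
    X = featurize(records)
    return records, pairs, truth, X


@pytest.fixture(scope="session")
def small_graph(small_planted):
    records, pairs, _, X = small_planted
    return build_graph(records, pairs, X)


@pytest.fixture
def tiny_records():
    return [
        RNARecord(id="a", sequence="ACGUACGU", kind="miRNA"),
        RNARecord(id="b", sequence="GGGCCCAU", kind="lncRNA"),
        RNARecord(id="c", sequence="AUAUAUGC", kind="lncRNA"),
    ]
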