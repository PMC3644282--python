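import numpy as np
import pytest

from ctxnet.io import GeneSetCollection, TrinaryMatrix


@pytest.fixture
def small_trinary():
    """3 genes x 2 samples with all three states."""
    values = np.array([[1, -1], [0, 1], [-1, 0]], dtype=np.int8)
    return TrinaryMatrix(values, ["g1", "g2", "g3"], ["s1", "s2"])


@pytest.fixture
def copied_pair_data():
    """Two perfectly dependent variables plus noise variables, 200 samples."""
    rng = np.random.default_rng(0)
    vals = rng.integers(-1, 2, size=(5, 200)).astype(np.int8)
    vals[1] = vals[0]
    return TrinaryMatrix(
        vals, ["A", "B", "C", "D", "E"], [f"s{i}" for i in range(200)]
    )


@pytest.fixture
def gene_sets():
    return GeneSetCollection(
        sets={"S1": frozenset({"g1", "g2"}), "S2": frozenset({"g3"})},
        descriptions={"S1": "first", "S2": "second"},
    )
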