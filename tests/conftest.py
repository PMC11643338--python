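import numpy as np
import pytest

from cliffaware import MoleculeRecord, featurize_batch


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_records():
    return [
        MoleculeRecord("CCO", 6.0),
        MoleculeRecord("c1ccccc1", 7.5),
        MoleculeRecord("C", 5.0),
        MoleculeRecord("CC(=O)O", 5.2),
        MoleculeRecord("c1ccncc1", 8.8),
        MoleculeRecord("CCN", 6.1),
    ]


@pytest.fixture
def small_batch(small_records):
    return featurize_batch(small_records)
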