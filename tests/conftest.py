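import numpy as np
import pytest

from apopred import LabeledDataset, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    records = [
        ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY" * 2),
        ProteinRecord("p2", "AAAACCCCDDDDEEEEFFFF"),
        ProteinRecord("p3", "MKTAYIAKQRQISFVKSHFS"),
    ]
    return LabeledDataset(records, ["ApoA", "ApoB", "ApoA"],
                          ("ApoA", "ApoB"))
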