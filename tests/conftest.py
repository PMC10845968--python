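import numpy as np
import pandas as pd
import pytest

from endocore import synth
from endocore.io import AbundanceTable, CompoundTable, SampleMetadata


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3], [2, 4, 3], [1, 1, 2]],
        index=["s1", "s2", "s3"],
        columns=["ta", "tb", "tc"],
    )
    return AbundanceTable(counts)


@pytest.fixture
def small_meta():
    frame = pd.DataFrame(
        {"group": ["A", "A", "B"], "replicate": [1, 2, 1]},
        index=["s1", "s2", "s3"],
    )
    return SampleMetadata(frame)


@pytest.fixture(scope="session")
def demo_dataset():
    """One deterministic 12-sample synthetic dataset shared across tests."""
    cfg = synth.SynthConfig(n_taxa=30, seed=7)
    return synth.generate_dataset(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
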