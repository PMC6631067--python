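import numpy as np
import pytest
from hypothesis import settings

from heartedge import extract_matrix, generate_dataset
from heartedge.synth import (
    DEFAULT_MURMUR_INTENSITY,
    DEFAULT_SPIKE_RATE,
    SynthParams,
)

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")

#: the default study dataset: balanced 100+100, 10 s at 2000 Hz, master seed 42
DATASET_SEED = 42


@pytest.fixture(scope="session")
def dataset200():
    return generate_dataset(100, 100, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def fm200(dataset200):
    return extract_matrix(dataset200)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick 10+10 dataset of 5 s records for unit and CLI tests."""
    template = SynthParams(
        duration_s=5.0,
        murmur_intensity=DEFAULT_MURMUR_INTENSITY,
        spike_rate_per_s=DEFAULT_SPIKE_RATE,
    )
    return generate_dataset(10, 10, template, seed=3)


def stratified_split(fm, train_fraction=0.7, seed=1):
    """70/30 split preserving class balance; returns (train, test)."""
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = [], []
    for cls in (1, -1):
        idx = np.flatnonzero(fm.labels == cls)
        rng.shuffle(idx)
        k = int(round(train_fraction * idx.size))
        tr_idx.extend(idx[:k])
        te_idx.extend(idx[k:])
    return fm.subset(sorted(tr_idx)), fm.subset(sorted(te_idx))
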