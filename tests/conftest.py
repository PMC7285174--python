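import numpy as np
import pytest

from shocknet.dataset import balance_by_replication, build_split
from shocknet.rhythms import RhythmClass as R
from shocknet.synthetic import generate_dataset


@pytest.fixture(scope="session")
def tiny_archives():
    """Small train/validation strip collections (distinct patient pools)."""
    counts = {R.VF: 12, R.VT: 4, R.NSR: 16, R.ONR: 20, R.ASYS: 12}
    train = generate_dataset(counts, seed=11, patient_prefix="TR")
    val = generate_dataset(counts, seed=22, patient_prefix="VA")
    return train, val


@pytest.fixture(scope="session")
def tiny_splits(tiny_archives):
    """2 s analysis windows at 125 Hz, shockables replicated 4x for training."""
    train, val = tiny_archives
    tr = balance_by_replication(build_split(train, 2.0, "TRAIN"), 4)
    va = build_split(val, 2.0, "VALIDATION")
    return tr, va


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
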