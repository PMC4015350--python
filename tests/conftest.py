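import numpy as np
import pytest
from hypothesis import settings

import riskmachines as rm

settings.register_profile("suite", derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model1_data():
    """One model-1 dataset at the study's standard size."""
    return rm.simulate(rm.builtin_model("model1"), 1000, seed=101)


@pytest.fixture(scope="session")
def model5_data():
    return rm.simulate(rm.builtin_model("model5"), 1000, seed=102)


@pytest.fixture()
def tiny_data():
    """A 200-subject two-feature dataset for fast fits."""
    rng = np.random.default_rng(7)
    X = (rng.random((200, 2)) < 0.5).astype(int)
    y = (rng.random(200) < 0.3 + 0.4 * X[:, 0]).astype(int)
    return rm.BinaryDataset(y=y, X=X, feature_names=("X1", "X2"))
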