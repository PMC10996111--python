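import numpy as np
import pandas as pd
import pytest

from daebls import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(X, y=None, columns=None):
    X = np.asarray(X, dtype=float)
    cols = columns or [f"f{j}" for j in range(X.shape[1])]
    return FeatureTable(pd.DataFrame(X, columns=cols),
                        None if y is None else pd.Series(y))


@pytest.fixture
def tiny_labelled():
    return make_table(
        [[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [2.0, 2.0], [2.1, 1.9], [1.9, 2.1]],
        y=[0, 0, 0, 1, 1, 1],
    )
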