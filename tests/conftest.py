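import numpy as np
import pytest

import fermopt as fo


@pytest.fixture(scope="session")
def table1():
    return fo.table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return fo.table2_fixture()


@pytest.fixture(scope="session")
def table1_scaler(table1):
    return fo.fit_scaler(table1)


@pytest.fixture(scope="session")
def table1_scaled(table1, table1_scaler):
    """(X, y) of the 25 training conditions in scaled units."""
    X = table1_scaler.transform_features(table1.X)
    y = table1_scaler.transform_target(table1.y)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
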