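import numpy as np
import pytest

from flavopgp import data as d
from flavopgp.qsar import fit_ols


@pytest.fixture(scope="session")
def descriptors():
    return d.load_fixture("descriptors")


@pytest.fixture(scope="session")
def cytotoxicity():
    return d.load_fixture("cytotoxicity")


@pytest.fixture(scope="session")
def responses():
    return d.response_table()


@pytest.fixture(scope="session")
def split_tables(descriptors, responses):
    return d.split_train_test(descriptors, responses, d.SplitSpec.default())


@pytest.fixture(scope="session")
def y_train(split_tables):
    return split_tables.train_response["ic50"].to_numpy()


@pytest.fixture(scope="session")
def y_test(split_tables):
    return split_tables.test_response["ic50"].to_numpy()


@pytest.fixture(scope="session")
def trained_model(split_tables, y_train):
    return fit_ols(split_tables.train_descriptors, y_train)


def random_design(rng: np.random.Generator, n: int, k: int):
    """Well-conditioned random regression problem for oracle comparisons."""
    X = rng.standard_normal((n, k)) * rng.uniform(0.5, 3.0, size=k)
    beta = rng.uniform(-3, 3, size=k)
    y = X @ beta + rng.uniform(-2, 2) + 0.3 * rng.standard_normal(n)
    return X, y
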