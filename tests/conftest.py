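import numpy as np
import pandas as pd
import pytest

from eagafs.dataset_io import AttributeSpec, TabularDataset
from eagafs.synthetic import SyntheticSpec, generate, worked_example_fixture


@pytest.fixture
def worked_example():
    return worked_example_fixture()


@pytest.fixture
def worked_example_labelled():
    return worked_example_fixture(labels="plas-threshold")


@pytest.fixture
def small_synthetic():
    """300-row table with 3 strong and 2 noise attributes."""
    return generate(SyntheticSpec(n_rows=300, n_informative=3, n_noise=2,
                                  effect_size=2.0, seed=11))


def make_numeric_dataset(X: np.ndarray, y, names=None) -> TabularDataset:
    """Wrap a plain numeric matrix as a TabularDataset."""
    X = np.asarray(X, dtype=float)
    names = names or [f"a{j}" for j in range(X.shape[1])]
    return TabularDataset(
        schema=[AttributeSpec(n, "numeric") for n in names],
        X=pd.DataFrame(X, columns=names),
        labels=np.asarray(y, dtype=int),
    )


@pytest.fixture
def numeric_dataset_factory():
    return make_numeric_dataset
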