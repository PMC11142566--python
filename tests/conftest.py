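import numpy as np
import pytest

from clusterbalance import (
    FeatureSchema,
    GeneratorConfig,
    LabeledTable,
    clean,
    generate,
    standardize,
)
from clusterbalance.tabular import CONTINUOUS


def make_table(X, y, kinds=None):
    """LabeledTable from raw arrays with a throwaway schema."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    d = X.shape[1]
    kinds = kinds or (CONTINUOUS,) * d
    schema = FeatureSchema(
        tuple(f"f{i}" for i in range(d)), tuple(kinds), "label", "yes", "no"
    )
    return LabeledTable(X, np.asarray(y, int), schema)


@pytest.fixture
def toy_imbalanced():
    """Two Gaussian blobs, 180 vs 20 rows, mildly overlapping."""
    rng = np.random.default_rng(42)
    X0 = rng.normal(0.0, 1.0, size=(180, 3))
    X1 = rng.normal(1.5, 1.0, size=(20, 3))
    X = np.vstack([X0, X1])
    y = np.array([0] * 180 + [1] * 20)
    return make_table(X, y)


@pytest.fixture(scope="session")
def default_table():
    """Cleaned + standardized default synthetic table (one per session)."""
    table = clean(generate(GeneratorConfig(seed=123)))
    (ts,), _ = standardize(table)
    return ts
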