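import numpy as np
import pytest

from deltamem import AttributeSchema, FundamentalSet


def make_fs(X, y, class_names=None, schema=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if class_names is None:
        class_names = [f"class{c}" for c in range(int(y.max()) + 1)]
    if schema is None:
        schema = [AttributeSchema(name=f"a{j}") for j in range(X.shape[1])]
    return FundamentalSet(X, y, schema, class_names)


def random_conflict_free_fs(rng, p_max=200, n_max=13, n_classes=2, integral=True):
    """A random fundamental set with no duplicate pattern under two labels."""
    p = int(rng.integers(max(n_classes, 2), p_max + 1))
    n = int(rng.integers(1, n_max + 1))
    while True:
        if integral:
            X = rng.integers(-20, 21, size=(p, n)).astype(float)
        else:
            X = np.round(rng.normal(0, 10, size=(p, n)), 3)
        y = rng.integers(0, n_classes, size=p)
        # ensure every class is present
        y[:n_classes] = np.arange(n_classes)
        # conflict-free: deduplicate rows by keeping the first label
        _, first = np.unique(X, axis=0, return_index=True)
        keep = np.zeros(p, dtype=bool)
        keep[first] = True
        X, y = X[keep], y[keep]
        if len(np.unique(y)) == n_classes and len(y) >= n_classes:
            return make_fs(X, y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_fs():
    """Two well-separated classes, four patterns."""
    return make_fs(
        [[0, 0], [1, 0], [10, 10], [11, 10]],
        [0, 0, 1, 1],
        class_names=["absence", "presence"],
    )
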