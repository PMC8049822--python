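import numpy as np
import pytest

from redpep.alphabets import load_builtin_family
from redpep.encoding import FeatureMatrix, ProteinRecord


@pytest.fixture(scope="session")
def family():
    return load_builtin_family()


@pytest.fixture(scope="session")
def size2(family):
    return family[0]


@pytest.fixture(scope="session")
def size10(family):
    return next(s for s in family if s.size == 10)


@pytest.fixture(scope="session")
def size19(family):
    return next(s for s in family if s.size == 19)


def make_matrix(values, labels, feature_names=None, scheme=None, n=2):
    """Assemble a FeatureMatrix by hand for model/selection tests."""
    values = np.asarray(values, dtype=np.float64)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(values.shape[1])]
    if scheme is None:
        scheme = load_builtin_family()[0]
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        feature_names=list(feature_names),
        values=values,
        labels=np.asarray(labels, dtype=np.int64),
        scheme=scheme,
        n=n,
    )


@pytest.fixture
def separable_matrix():
    """Two clusters far apart in feature 0; the rest is noise."""
    rng = np.random.default_rng(7)
    n = 40
    X = rng.normal(size=(n, 5)) * 0.05
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X[:, 0] += y * 5.0
    return make_matrix(X, y)


def random_records(rng, n, label, lo=30, hi=80):
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    recs = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length))
        recs.append(ProteinRecord(f"{'p' if label else 'n'}{i}", seq, label))
    return recs
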