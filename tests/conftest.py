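import numpy as np
import pytest

from enosecnn import (
    FeatureMatrix,
    HyperParams,
    generate,
    make_spec_separated,
    normalize_minmax,
)


@pytest.fixture
def four_class_norm():
    """Four well-separated synthetic classes, min-max normalized."""
    spec = make_spec_separated(4, seed=42)
    X, labels, _ = generate(spec)
    Xn, params = normalize_minmax(X)
    return Xn, np.asarray(labels), params


@pytest.fixture
def five_class_holdout():
    """Four training classes plus a held-out fifth, raw volts."""
    spec = make_spec_separated(5, seed=7, holdout_class=4)
    X, labels, holdout = generate(spec)
    assert holdout is not None
    return X, np.asarray(labels), holdout[0]


@pytest.fixture
def default_hp():
    return HyperParams()


@pytest.fixture
def tiny_matrix():
    return FeatureMatrix(np.array([[1.0, 2.0], [3.0, 2.0], [5.0, 2.0]]))
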