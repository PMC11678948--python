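import numpy as np
import pytest

from spiralfs.synthetic import SyntheticSpec, make_classification_data


@pytest.fixture(scope="session")
def toy8():
    """Well-separated 8-feature dataset (3 informative) for oracle checks."""
    spec = SyntheticSpec(n_samples=60, n_features=8, n_informative=3,
                         effect_size=3.0, seed=11)
    return make_classification_data(spec)


@pytest.fixture(scope="session")
def separable2d():
    """Two point clouds with inter-class distance far above the spread."""
    rng = np.random.default_rng(0)
    x0 = rng.normal(0.0, 0.1, size=(30, 2))
    x1 = rng.normal(10.0, 0.1, size=(30, 2))
    x = np.vstack([x0, x1])
    y = np.repeat([0, 1], 30)
    return x, y


def sphere(x):
    return float(np.sum((x - 0.5) ** 2))
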