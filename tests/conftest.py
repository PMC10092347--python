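import numpy as np
import pytest

import surrogate_rsq as sr


@pytest.fixture(scope="session")
def setting1_data():
    """One moderate setting-1 draw (p=10 equicorrelated, J=3)."""
    data, z = sr.gen_setting1(600, seed=42)
    return data, z


@pytest.fixture(scope="session")
def setting1_fit(setting1_data):
    data, _ = setting1_data
    return sr.fit_probit(data)


@pytest.fixture(scope="session")
def binary_data():
    """Binary probit data with two informative covariates."""
    rng = np.random.default_rng(7)
    n = 500
    X = rng.standard_normal((n, 2))
    z = 0.3 + 1.2 * X[:, 0] - 0.8 * X[:, 1] + rng.standard_normal(n)
    y = (z > 0).astype(int) + 1
    return sr.OrdinalDataset.from_arrays(X, y, var_names=("a", "b"), name="binary"), z


@pytest.fixture()
def toy_dataset():
    """Tiny deterministic 10-row, J=3 dataset for brute-force oracles."""
    X = np.array([[0.5, -1.0], [1.5, 0.2], [-0.3, 0.8], [2.0, -0.5], [0.0, 0.0],
                  [-1.2, 1.1], [0.7, 0.7], [-0.9, -0.4], [1.1, -1.3], [0.4, 2.0]])
    y = np.array([1, 3, 2, 3, 2, 1, 2, 1, 3, 2])
    return sr.OrdinalDataset.from_arrays(X, y, var_names=("u", "v"), name="toy")
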