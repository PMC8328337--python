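import numpy as np
import pandas as pd
import pytest

import phlsm


@pytest.fixture
def triangle_net():
    """3-node network with edges {1->2, 3->2, 2->1}."""
    Y = np.zeros((3, 3), dtype=int)
    Y[0, 1] = 1
    Y[2, 1] = 1
    Y[1, 0] = 1
    return phlsm.DirectedNetwork(["v1", "v2", "v3"], Y)


@pytest.fixture
def small_attrs():
    frame = pd.DataFrame(
        {"age": [0.2, 0.2 * np.e, 1.0], "sex": ["M", "F", "M"]},
        index=["v1", "v2", "v3"])
    return phlsm.AttributeTable(frame, {"age": "continuous", "sex": "categorical"})


@pytest.fixture
def toy_fit():
    """A 4-node network with one covariate plus consistent model states."""
    rng = np.random.default_rng(42)
    Y = np.array([[0, 1, 0, 1],
                  [1, 0, 1, 0],
                  [0, 0, 0, 1],
                  [1, 0, 1, 0]])
    net = phlsm.DirectedNetwork(list("abcd"), Y)
    X = phlsm.PairwiseCovariates(
        np.abs(rng.normal(size=(1, 4, 4))) * (1 - np.eye(4)), [("a1", "continuous")])
    X.tensor[0] = (X.tensor[0] + X.tensor[0].T) / 2
    lat = phlsm.LatentState(rng.normal(size=(4, 2)), sigma2=0.5)
    reg = phlsm.RegressionState(np.array([0.3]), penalty="ridge", tau2=np.array([2.0]))
    pop = phlsm.PopularityState(np.array([0.4, 0.3, 0.2, 0.1]))
    hyper = phlsm.Hyperparams(phi=0.5)
    return net, X, lat, reg, pop, hyper
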