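import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mcpca import DiscreteMatrix, SimConfig, sim_admixed_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_discrete(rng):
    """A modest random discrete matrix with 3 categories per feature."""
    labels = rng.integers(0, 3, size=(80, 6))
    return DiscreteMatrix.from_labels(labels)


@pytest.fixture
def three_pop_genotypes():
    """Small, strongly differentiated 3-population genotype matrix."""
    cfg = SimConfig(n_per_pop=20, p_sites=300, fst=0.35, seed=7)
    X, labels, kept = sim_admixed_genotypes(cfg)
    return X, labels


def cluster_agreement(pred, true):
    """Best-permutation label agreement between two clusterings."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    k = int(max(pred.max(), true.max())) + 1
    C = np.zeros((k, k))
    np.add.at(C, (pred, true), 1)
    r, c = linear_sum_assignment(-C)
    return C[r, c].sum() / len(true)


@pytest.fixture
def agreement():
    return cluster_agreement
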