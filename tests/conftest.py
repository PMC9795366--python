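import numpy as np
import pytest
from hypothesis import settings

from gsem import AssociationMatrix, GsemHyperparams, build_graph

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


def random_instance(rng, n, m, density=0.4):
    """Random binary association matrix with no empty rows/columns."""
    while True:
        x = (rng.random((n, m)) < density).astype(float)
        if (x.sum(axis=1) > 0).all() and (x.sum(axis=0) > 0).all():
            break
    drugs = tuple(f"d{i}" for i in range(n))
    ses = tuple(f"s{j}" for j in range(m))
    return AssociationMatrix(drugs, ses, x)


def random_graph(rng, ids, name, p=0.5):
    edges = []
    ids = list(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rng.random() < p:
                edges.append((ids[i], ids[j], float(rng.uniform(0.1, 2.0))))
    return build_graph(ids, edges, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_X():
    return AssociationMatrix(("a", "b"), ("u", "v"), [[1.0, 0.0], [1.0, 1.0]])


@pytest.fixture(scope="session")
def fitted_small_model():
    """A converged 10x8 fit shared by the explanation/prediction tests."""
    from gsem import fit_gsem

    rng = np.random.default_rng(77)
    X = random_instance(rng, 10, 8)
    params_h = GsemHyperparams(l2=2.0, l1=0.05, tol=1e-5, max_iter=5000, seed=1)
    params_w = GsemHyperparams(l2=2.0, l1=0.05, tol=1e-5, max_iter=5000, seed=2)
    h, w, traces = fit_gsem(X, [], [], params_h, params_w)
    return X, h, w, traces
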