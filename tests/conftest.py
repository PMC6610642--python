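import numpy as np
import pytest

import wgrmf as w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_dataset():
    """The reference synthetic fixture used across solver/evaluation tests:
    rank-2 truth, noise at 0.1·sd, 20% of entries masked."""
    return w.generate(n=25, m=40, k_true=2, noise_sd=0.1, missing_fraction=0.2, seed=0)


@pytest.fixture(scope="session")
def standard_hp():
    return w.HyperParams(k=2, lambda_l=0.25, lambda_d=0.125, lambda_c=0.125,
                         p_drug=5, p_cell=5)


def random_similarity(rng, n):
    """Random nonnegative symmetric similarity with unit diagonal."""
    S = np.abs(np.corrcoef(rng.standard_normal((n, max(5, n)))))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def tiny_problem(rng, n, m, k):
    """Small random masked problem plus similarity matrices and Laplacians."""
    from wgrmf.graph import build_pnn_graph, laplacians, sparsify

    R = rng.standard_normal((n, m))
    W = (rng.random((n, m)) < 0.8).astype(float)
    W[W.sum(axis=1) == 0, 0] = 1.0
    W[0, W.sum(axis=0) == 0] = 1.0
    rm = w.ResponseMatrix([f"d{i}" for i in range(n)],
                          [f"c{j}" for j in range(m)], R, W)
    Sd = random_similarity(rng, n)
    Sc = random_similarity(rng, m)
    pd_, pc_ = min(2, n - 1), min(2, m - 1)
    Ld = laplacians(sparsify(Sd, build_pnn_graph(Sd, pd_))).L_tilde
    Lc = laplacians(sparsify(Sc, build_pnn_graph(Sc, pc_))).L_tilde
    return rm, Sd, Sc, Ld, Lc
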