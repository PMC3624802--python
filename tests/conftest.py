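import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(seed, d_max=200, k_max=20, k_fixed=None):
    """Random normalized profile + column-stochastic signature matrix."""
    from domainmix.containers import DomainProfile, SignatureMatrix, _fixed_point_normalize

    g = np.random.default_rng(seed)
    d = int(g.integers(5, d_max + 1))
    k = int(k_fixed) if k_fixed else int(g.integers(2, k_max + 1))
    cols = g.dirichlet(np.full(d, 0.5), size=k).T
    cols = cols / cols.sum(axis=0)
    cols = cols / cols.sum(axis=0)
    fams = [f"PF{i:05d}" for i in range(d)]
    refs = SignatureMatrix(fams, [f"s{i}" for i in range(k)], cols)
    y = g.dirichlet(np.full(d, 0.7))
    if g.random() < 0.5:  # exercise the supported-family restriction
        y[g.random(d) < 0.2] = 0.0
        if y.sum() == 0:
            y[0] = 1.0
    profile = DomainProfile(fams, _fixed_point_normalize(y))
    return profile, refs


def naive_loglik(y, X, w):
    """Independent per-family loop oracle for the mixture log-likelihood."""
    supported = [j for j in range(len(y)) if y[j] > 0 and X[j].sum() > 0]
    ysum = sum(y[j] for j in supported)
    total = 0.0
    for j in supported:
        p = sum(w[i] * X[j, i] for i in range(X.shape[1]))
        total += (y[j] / ysum) * np.log(max(p, 1e-300))
    return total


def grid_search_loglik(y, X, step=0.01):
    """Best mixture log-likelihood over a simplex grid (K=3 only)."""
    assert X.shape[1] == 3
    supported = (y > 0) & (X.sum(axis=1) > 0)
    yr = y[supported] / y[supported].sum()
    Xs = X[supported]
    w1 = np.arange(0, 1 + step / 2, step)
    ws = []
    for a in w1:
        for b in np.arange(0, 1 - a + step / 2, step):
            ws.append((a, b, max(1.0 - a - b, 0.0)))
    W = np.array(ws).T  # 3 x G
    P = np.maximum(Xs @ W, 1e-300)
    return float(np.max(yr @ np.log(P)))
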