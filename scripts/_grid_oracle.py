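"""Independent oracles used by the acceptance script.

Kept separate from the package so the checks do not share code with the
implementation they validate.
"""

import numpy as np

from domainmix.containers import DomainProfile, SignatureMatrix, _fixed_point_normalize


def random_instance(seed, d_max=200, k_max=20, k_fixed=None):
    g = np.random.default_rng(seed)
    d = int(g.integers(5, d_max + 1))
    k = int(k_fixed) if k_fixed else int(g.integers(2, k_max + 1))
    cols = g.dirichlet(np.full(d, 0.5), size=k).T
    cols = cols / cols.sum(axis=0)
    cols = cols / cols.sum(axis=0)
    fams = [f"PF{i:05d}" for i in range(d)]
    refs = SignatureMatrix(fams, [f"s{i}" for i in range(k)], cols)
    y = g.dirichlet(np.full(d, 0.7))
    if g.random() < 0.5:
        y[g.random(d) < 0.2] = 0.0
        if y.sum() == 0:
            y[0] = 1.0
    return DomainProfile(fams, _fixed_point_normalize(y)), refs


def grid_search_loglik(y, X, step=0.01):
    """Exhaustive simplex grid maximization of the mixture log-likelihood."""
    assert X.shape[1] == 3
    supported = (y > 0) & (X.sum(axis=1) > 0)
    yr = y[supported] / y[supported].sum()
    Xs = X[supported]
    ws = []
    for a in np.arange(0, 1 + step / 2, step):
        for b in np.arange(0, 1 - a + step / 2, step):
            ws.append((a, b, max(1.0 - a - b, 0.0)))
    W = np.array(ws).T
    P = np.maximum(Xs @ W, 1e-300)
    return float(np.max(yr @ np.log(P)))
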