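"""Independent reference implementations used only to check the package.

Each oracle computes its quantity from the mathematical definition by a
different route than the implementation under test: alternating NNLS for
the joint factorization objective, exact combinatorial enumeration for the
hypergeometric tail, the textbook step-up recursion for Benjamini-Hochberg,
and the covariance-ratio definition of Pearson r.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.optimize import nnls


def anls_joint(Xs: list[np.ndarray], K: int, seed: int, n_starts: int = 5,
               max_sweeps: int = 200, tol: float = 1e-9) -> float:
    """Best objective over ``n_starts`` of alternating non-negative least
    squares on the stacked problem [X_1 X_2 X_3] ~ W [H_1 H_2 H_3]."""
    Xcat = np.hstack(Xs)
    M = Xs[0].shape[0]
    best = np.inf
    for s in range(n_starts):
        rng = np.random.default_rng(seed + 1000 + s)
        W = 1.0 - rng.random((M, K))
        Hs = [1.0 - rng.random((K, X.shape[1])) for X in Xs]
        prev = np.inf
        for _ in range(max_sweeps):
            Hcat = np.hstack(Hs)
            W = np.vstack([nnls(Hcat.T, Xcat[i, :])[0] for i in range(M)])
            for li, X in enumerate(Xs):
                Hs[li] = np.column_stack(
                    [nnls(W, X[:, j])[0] for j in range(X.shape[1])])
            f = sum(float(np.linalg.norm(X - W @ H) ** 2)
                    for X, H in zip(Xs, Hs))
            if prev - f < tol * max(f, 1.0):
                break
            prev = f
        best = min(best, f)
    return best


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int,
                         draws: int) -> float:
    """P(X >= overlap) by exact enumeration of the hypergeometric pmf."""
    total = comb(universe, draws)
    acc = 0
    for x in range(overlap, min(set_size, draws) + 1):
        if draws - x > universe - set_size:
            continue
        acc += comb(set_size, x) * comb(universe - set_size, draws - x)
    return acc / total


def bh_stepup(pvals: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg: q_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvals[i] / rank))
        adjusted[i] = running
    return adjusted


def pearson_r(x, y) -> float:
    """Pearson r straight from the covariance / sigma definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).sum()
    return float(cov / np.sqrt(((x - x.mean()) ** 2).sum()
                               * ((y - y.mean()) ** 2).sum()))
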