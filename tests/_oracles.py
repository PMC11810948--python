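"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths (and networkx's
modularity helper): modularity is computed straight from the adjacency
matrix, partitions are enumerated as restricted-growth strings, and
Blomberg's K is written out with explicit matrix inversion.
"""

from __future__ import annotations

import numpy as np


def modularity_from_adjacency(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman's Q = sum_c [e_c/m - (d_c/2m)^2] from a 0/1 adjacency matrix."""
    adj = np.asarray(adj)
    deg = adj.sum(axis=1)
    two_m = deg.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = adj[np.ix_(mask, mask)].sum() / 2.0
        d_c = deg[mask].sum()
        q += e_c / (two_m / 2.0) - (d_c / two_m) ** 2
    return q


def restricted_growth_strings(n: int):
    """All set partitions of range(n), encoded as label vectors."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def brute_force_max_modularity(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive maximum-modularity partition of a small graph."""
    n = adj.shape[0]
    best_q, best = -np.inf, None
    for labels in restricted_growth_strings(n):
        q = modularity_from_adjacency(adj, labels)
        if q > best_q + 1e-12:
            best_q, best = q, labels
    return best_q, best


def naive_blomberg_k(C: np.ndarray, x: np.ndarray) -> float:
    """K written directly from its definition with an explicit inverse."""
    n = len(x)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a_hat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    d = x - a_hat
    mse0 = d @ d / (n - 1)
    mse = d @ Cinv @ d / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def sequential_f_tests(y: np.ndarray, g: np.ndarray, z: np.ndarray):
    """Type-I F tests for y ~ g + z + g:z by nested least-squares fits.

    ``g`` is a 0/1 group indicator, ``z`` a continuous covariate.  Returns
    {(name): (F, df1)} with the full-model residual MS as denominator.
    """
    n = len(y)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    one = np.ones(n)
    designs = [
        np.column_stack([one]),
        np.column_stack([one, g]),
        np.column_stack([one, g, z]),
        np.column_stack([one, g, z, g * z]),
    ]
    rss_seq = [rss(X) for X in designs]
    df_resid = n - designs[-1].shape[1]
    mse_full = rss_seq[-1] / df_resid
    names = ["factor", "elevation", "interaction"]
    return {
        name: ((rss_seq[i] - rss_seq[i + 1]) / 1.0) / mse_full for i, name in enumerate(names)
    }, df_resid
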