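"""Independent brute-force oracles, kept deliberately naive.

These re-derive quantities with direct loops and textbook formulas so the
vectorized implementations can be checked against them. They share no code
with the package internals.
"""

import numpy as np


def sliding_median3(x):
    """3-sample sliding median; edge samples pass through."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    for i in range(1, len(x) - 1):
        out[i] = sorted(x[i - 1 : i + 2])[1]
    return out


def autocov_normalized(x, lag):
    """Unbiased autocovariance at one lag, normalized by lag 0, double loop."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x0 = x - sum(x) / n
    num = 0.0
    for t in range(n - lag):
        num += x0[t] * x0[t + lag]
    num /= n - lag
    den = sum(v * v for v in x0) / n
    return num / den


def peak_prominence(p, i):
    """Prominence of the local maximum at index i: walk down each side until
    a strictly higher bar (or the edge); the higher of the two interval
    minima is the base."""
    p = np.asarray(p, dtype=float)
    left_min = p[i]
    j = i - 1
    while j >= 0 and p[j] <= p[i]:
        left_min = min(left_min, p[j])
        j -= 1
    right_min = p[i]
    j = i + 1
    while j < len(p) and p[j] <= p[i]:
        right_min = min(right_min, p[j])
        j += 1
    return p[i] - max(left_min, right_min)


def relieff_exhaustive(X, y, K):
    """Direct ReliefF: all instances, Manhattan distance, K hits/misses,
    two-class prior-weighted miss term, ties by ascending index."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    m, p = X.shape
    priors = {c: np.sum(y == c) / m for c in (0, 1)}
    W = np.zeros(p)
    for i in range(m):
        dists = [(sum(abs(X[i, f] - X[j, f]) for f in range(p)), j) for j in range(m)]
        for cls in (0, 1):
            cands = sorted((d, j) for d, j in dists if j != i and y[j] == cls)
            nbrs = [j for _, j in cands[:K]]
            for f in range(p):
                s = sum(abs(X[i, f] - X[j, f]) for j in nbrs) / (m * K)
                if cls == y[i]:
                    W[f] -= s
                else:
                    W[f] += priors[cls] / (1.0 - priors[y[i]]) * s
    return W
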