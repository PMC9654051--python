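"""Independent brute-force references used by the weighting and acceptance
tests: direct scalar-loop formula evaluation, deliberately sharing no code
with the implementation."""

import math

import numpy as np


def oracle_weights(table) -> dict[str, float]:
    """Entropy/Gini/chi-square family evaluated straight from the formulas."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    rows, cols = t.shape

    def H(probs):
        return -sum(p * math.log2(p) for p in probs if p > 0)

    def gini(probs):
        return 1.0 - sum(p * p for p in probs)

    p_bin = [t[b, :].sum() / n for b in range(rows)]
    p_cls = [t[:, c].sum() / n for c in range(cols)]
    h_cls, h_bin = H(p_cls), H(p_bin)
    cond_h = cond_g = 0.0
    for b in range(rows):
        nb = t[b, :].sum()
        if nb > 0:
            probs = [t[b, c] / nb for c in range(cols)]
            cond_h += (nb / n) * H(probs)
            cond_g += (nb / n) * gini(probs)
    ig = h_cls - cond_h
    chi2 = 0.0
    for b in range(rows):
        for c in range(cols):
            e = t[b, :].sum() * t[:, c].sum() / n
            if e > 0:
                chi2 += (t[b, c] - e) ** 2 / e
    return {
        "info_gain": max(0.0, ig),
        "info_gain_ratio": max(0.0, ig / h_bin) if h_bin > 0 else 0.0,
        "uncertainty": max(0.0, 2 * ig / (h_cls + h_bin)) if h_cls + h_bin > 0 else 0.0,
        "gini_index": max(0.0, gini(p_cls) - cond_g),
        "chi_squared": chi2,
    }


def oracle_relief(X, y, numeric, k: int) -> np.ndarray:
    """Brute-force ReliefF: O(n^2) scalar loops over instances, neighbours,
    and features; stable (distance, index) neighbour ordering."""
    X = np.asarray(X)
    n, p = X.shape
    scaled = X.astype(float).copy()
    for j in range(p):
        if numeric[j]:
            lo, hi = scaled[:, j].min(), scaled[:, j].max()
            scaled[:, j] = 0.0 if hi == lo else (scaled[:, j] - lo) / (hi - lo)

    def diff(j, a, b):
        if numeric[j]:
            return abs(scaled[a, j] - scaled[b, j])
        return 0.0 if X[a, j] == X[b, j] else 1.0

    w = np.zeros(p)
    for i in range(n):
        dists = []
        for m in range(n):
            if m == i:
                continue
            d = sum(diff(j, i, m) for j in range(p))
            dists.append((d, m))
        dists.sort(key=lambda t: (t[0], t[1]))
        hits = [m for _, m in dists if y[m] == y[i]][:k]
        misses = [m for _, m in dists if y[m] != y[i]][:k]
        for j in range(p):
            w[j] += (sum(diff(j, i, m) for m in misses) / k
                     - sum(diff(j, i, h) for h in hits) / k)
    return w / n
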