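"""Independent reference implementations used only as test oracles.

These deliberately use the most literal formulation of each quantity
(explicit pairwise template matching, exhaustive path sums, linear
nearest-neighbor scans) so they stay independent of the library's
vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def sampen_bruteforce(series, m: int, r: float) -> float:
    """O(N^2) pairwise template matcher for SampEn(m, r, N)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= m + 1:
        return float("nan")
    sd = x.std()
    x = np.zeros(n) if sd == 0 else (x - x.mean()) / sd
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def sampen_rowwise(series, m: int, r: float) -> float:
    """Faster O(N^2) matcher (row-at-a-time), same arithmetic as above."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= m + 1:
        return float("nan")
    sd = x.std()
    x = np.zeros(n) if sd == 0 else (x - x.mean()) / sd
    nt = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    b = a = 0
    for i in range(nt):
        dm = np.abs(tm - tm[i]).max(axis=1)
        dm1 = np.abs(tm1 - tm1[i]).max(axis=1)
        b += int((dm <= r).sum()) - 1
        a += int((dm1 <= r).sum()) - 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def forward_bruteforce(pi, A, B, obs) -> float:
    """P(O | lambda) by exhaustive summation over all N^T state paths."""
    pi, A, B = np.asarray(pi), np.asarray(A), np.asarray(B)
    n = pi.size
    total = 0.0
    for path in product(range(n), repeat=len(obs)):
        p = pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, len(obs)):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        total += p
    return total


def nearest_index_scan(vector, code_vectors) -> int:
    """Linear nearest-neighbor scan, lowest index on ties."""
    best, best_d = 0, float("inf")
    for j, c in enumerate(code_vectors):
        d = float(np.sum((np.asarray(vector) - np.asarray(c)) ** 2))
        if d < best_d:
            best, best_d = j, d
    return best


def random_hmm(n: int, m: int, rng: np.random.Generator):
    """A random valid (pi, A, B) triple."""
    A = rng.random((n, n)) + 0.05
    B = rng.random((n, m)) + 0.05
    pi = rng.random(n) + 0.05
    return pi / pi.sum(), A / A.sum(axis=1, keepdims=True), B / B.sum(axis=1, keepdims=True)
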