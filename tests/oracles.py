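"""Independent oracles used by the test suite.

Each routine recomputes a quantity by brute force (enumeration, exhaustive
dynamic programming, closed form or Monte Carlo) with no code shared with
the implementation it checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def local_alignment_score(a: str, b: str, match=1, mismatch=-1, gap_open=2, gap_extend=1) -> float:
    """Gotoh local alignment over DNA strings; a length-L gap costs
    gap_open + (L-1)*gap_extend.  Exhaustive over all local alignments."""
    n, m = len(a), len(b)
    neg = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def hypergeom_upper_tail_enumerated(N: int, K: int, n: int, k: int) -> float:
    """Pr(|A ∩ B| >= k) by enumerating every size-n draw B from a universe
    of N with A fixed as the first K elements.  Feasible for N <= 12."""
    universe = range(N)
    a = set(range(K))
    total = 0
    hits = 0
    for b in itertools.combinations(universe, n):
        total += 1
        if len(a & set(b)) >= k:
            hits += 1
    return hits / total


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition:
    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(1.0, q_sorted)
    return q


def order_statistic_cdf_monte_carlo(r, n_draws: int, rng: np.random.Generator):
    """Pr(U_(1) <= r_(1), ..., U_(n) <= r_(n)) by simulation; returns
    (estimate, standard error)."""
    r = np.sort(np.asarray(r, dtype=float))
    u = np.sort(rng.uniform(size=(n_draws, len(r))), axis=1)
    hit = np.all(u <= r[None, :], axis=1)
    p = hit.mean()
    se = math.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws)
    return p, se


def set_partitions(items):
    """All partitions of a list (Bell number many; fine for <= 8 items)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def newman_girvan_modularity(edges, partition) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) over communities, from first
    principles."""
    edges = list(edges)
    m = len(edges)
    if m == 0:
        return 0.0
    label = {}
    for c, block in enumerate(partition):
        for node in block:
            label[node] = c
    degree: dict = {}
    internal = [0] * len(partition)
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
        if label[a] == label[b]:
            internal[label[a]] += 1
    q = 0.0
    for c, block in enumerate(partition):
        d_c = sum(degree.get(node, 0) for node in block)
        q += internal[c] / m - (d_c / (2 * m)) ** 2
    return q


def null_law_of_pair_pvalue(t):
    """Distribution function of W = 2*U*V - min(U,V)^2 for iid U, V ~
    Uniform(0,1): the law of the two-species order-statistic p-value when
    each species' pair rank ratio is uniform under the global null.
    Derived in closed form by integrating over {(u, v): u < v}."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = (t > 0) & (t < 1)
    ti = t[inside]
    u0 = 1.0 - np.sqrt(1.0 - ti)
    out[inside] = 2.0 * (
        u0 - u0**2 / 2 + (ti / 2) * np.log(np.sqrt(ti) / u0) - (ti - u0**2) / 4
    )
    out[t >= 1] = 1.0
    return out
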