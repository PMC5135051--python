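"""Independent brute-force oracles used to validate the package's metrics.

Everything here is written straight from the defining formulas, favouring
clarity and exhaustiveness over speed, and deliberately shares no code with
the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator

import numpy as np


def iter_fixed_margin_matrices(r, c) -> Iterator[np.ndarray]:
    """All non-negative integer matrices with row sums r and column sums c,
    by brute-force enumeration of row compositions."""
    r = list(r)
    c = list(c)

    def compositions(total: int, caps: list[int]) -> Iterator[tuple[int, ...]]:
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in compositions(total - v, caps[1:]):
                yield (v, *rest)

    def rec(i: int, c_rem: list[int], rows: list[tuple[int, ...]]) -> Iterator[np.ndarray]:
        if i == len(r):
            if all(x == 0 for x in c_rem):
                yield np.array(rows, dtype=np.int64)
            return
        for comp in compositions(r[i], c_rem):
            rec_c = [a - b for a, b in zip(c_rem, comp)]
            yield from rec(i + 1, rec_c, rows + [comp])

    yield from rec(0, c, [])


def shannon_entropy(mat: np.ndarray) -> float:
    p = mat[mat > 0] / mat.sum()
    return float(-(p * np.log(p)).sum())


def h2prime_oracle(A: np.ndarray) -> float:
    """H2' by exhaustive enumeration of the margin-constrained extremes."""
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    entropies = [shannon_entropy(m) for m in iter_fixed_margin_matrices(r, c)]
    h_min, h_max = min(entropies), max(entropies)
    if h_max - h_min < 1e-12:
        return 0.0
    return (h_max - shannon_entropy(A)) / (h_max - h_min)


def wnodf_oracle(A: np.ndarray) -> float:
    """WNODF straight from its pairwise definition."""

    def pair_sum(M: np.ndarray) -> float:
        margins = M.sum(axis=1)
        order = sorted(range(M.shape[0]), key=lambda i: (-margins[i], i))
        M = M[order]
        margins = margins[order]
        s = 0.0
        for i in range(M.shape[0] - 1):
            for j in range(i + 1, M.shape[0]):
                if margins[i] <= margins[j]:
                    continue
                pos_j = [k for k in range(M.shape[1]) if M[j, k] > 0]
                if not pos_j:
                    continue
                k_ij = sum(1 for k in pos_j if M[j, k] < M[i, k])
                s += 100.0 * k_ij / len(pos_j)
        return s

    n_p, n_a = A.shape
    n_pairs = n_p * (n_p - 1) // 2 + n_a * (n_a - 1) // 2
    return (pair_sum(A.astype(float)) + pair_sum(A.T.astype(float))) / n_pairs


def horn_oracle(A: np.ndarray, guild: str = "ants") -> float:
    """Mean pairwise Morisita-Horn overlap from the closed-form formula."""
    V = A.T if guild == "ants" else A
    vals = []
    for i in range(V.shape[0] - 1):
        for j in range(i + 1, V.shape[0]):
            p = V[i] / V[i].sum()
            q = V[j] / V[j].sum()
            vals.append(2 * float((p * q).sum()) / float((p * p).sum() + (q * q).sum()))
    return float(np.mean(vals))


def modularity_oracle(A: np.ndarray, plant_mods, ant_mods) -> float:
    """Barber bipartite modularity by direct double summation."""
    F = A.sum()
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    q = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if plant_mods[i] == ant_mods[j]:
                q += A[i, j] / F - r[i] * c[j] / F**2
    return float(q)


def iter_set_partitions(items: list) -> Iterator[list[list]]:
    """All set partitions (restricted-growth enumeration)."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def rec(i: int, m: int) -> Iterator[list[int]]:
        if i == n:
            yield rgs.copy()
            return
        for v in range(m + 2):
            rgs[i] = v
            yield from rec(i + 1, max(m, v))

    for code in rec(1, 0):
        blocks: dict[int, list] = {}
        for item, b in zip(items, code):
            blocks.setdefault(b, []).append(item)
        yield list(blocks.values())


def exhaustive_best_partition(A: np.ndarray) -> tuple[float, dict]:
    """Global optimum of bipartite modularity over all species partitions."""
    n_p, n_a = A.shape
    nodes = list(range(n_p + n_a))
    best_q, best_assign = -np.inf, None
    for blocks in iter_set_partitions(nodes):
        assign = {}
        for b, members in enumerate(blocks):
            for v in members:
                assign[v] = b
        pm = [assign[i] for i in range(n_p)]
        am = [assign[n_p + j] for j in range(n_a)]
        q = modularity_oracle(A, pm, am)
        if q > best_q:
            best_q, best_assign = q, assign
    return best_q, best_assign


def permanova_exhaustive_oracle(D: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, exact p) by full enumeration of row permutations."""

    def pseudo_f(D2, g):
        n = len(g)
        sst = D2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for lab in set(g):
            idx = [i for i in range(n) if g[i] == lab]
            if len(idx) > 1:
                sub = D2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        a = len(set(g))
        return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

    D2 = D**2
    f_obs = pseudo_f(D2, list(groups))
    count, total = 0, 0
    for perm in itertools.permutations(range(len(groups))):
        g = [groups[i] for i in perm]
        if pseudo_f(D2, g) >= f_obs - 1e-12:
            count += 1
        total += 1
    return f_obs, count / total


def iter_all_matrices(shape: tuple[int, int], max_total: int) -> Iterator[np.ndarray]:
    """Every matrix of a given shape with positive margins and total <= max_total."""
    cells = shape[0] * shape[1]
    for total in range(1, max_total + 1):
        for cuts in itertools.combinations(range(total + cells - 1), cells - 1):
            vals = []
            prev = -1
            for cut in cuts:
                vals.append(cut - prev - 1)
                prev = cut
            vals.append(total + cells - 2 - prev)
            M = np.array(vals, dtype=np.int64).reshape(shape)
            if np.all(M.sum(axis=1) > 0) and np.all(M.sum(axis=0) > 0):
                yield M
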