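"""Network-level metrics for weighted bipartite interaction matrices.

Implements the four descriptors used throughout the pipeline:

* ``h2prime`` — complementary specialization H2', the two-dimensional
  Shannon entropy of the interaction-frequency distribution rescaled
  between the margin-constrained minimum- and maximum-entropy matrices.
  0 = interactions exactly at the independence expectation (maximal
  generalization), 1 = maximal specialization given the margins.
* ``wnodf`` — weighted nestedness based on overlap and decreasing fill
  (0-100): for every ordered pair of rows (and columns) with strictly
  decreasing totals, the share of the poorer row's positive cells that
  are positive-but-smaller in the richer row.
* ``horn_overlap`` — mean pairwise Morisita-Horn niche overlap among the
  members of one guild (ants by default), 0-1.
* ``degree_centrality`` — binary link counts per species.

All metrics require at least a 2x2 matrix (else the margin-conditional
reference distributions degenerate) and raise
:class:`~antweb.errors.UndefinedMetricError` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import UndefinedMetricError
from .network_model import LayerMatrix

__all__ = [
    "MetricValue",
    "h2prime",
    "wnodf",
    "horn_overlap",
    "degree_centrality",
]

#: Largest matrix total for which the H2' entropy bounds are obtained by
#: exhaustive enumeration of all margin-constrained integer matrices rather
#: than the heuristic fill.  Enumeration is exact but exponential.
H2_EXACT_TOTAL = 12


@dataclass(frozen=True)
class MetricValue:
    """A named network-level metric value with its matrix context."""

    name: str
    value: float
    matrix_shape: tuple[int, int]
    notes: str = ""

    def __float__(self) -> float:
        return float(self.value)


def _check_2x2(A: LayerMatrix, name: str) -> None:
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise UndefinedMetricError(
            f"{name} undefined on a {A.shape[0]}x{A.shape[1]} matrix "
            "(needs at least 2 plants and 2 ants)"
        )


# -- H2' --------------------------------------------------------------------


def _shannon(mat: np.ndarray) -> float:
    """Two-dimensional Shannon entropy of cell proportions p_ij = a_ij/F."""
    total = mat.sum()
    p = mat[mat > 0] / total
    return float(-(p * np.log(p)).sum())


def _iter_margin_matrices(r: np.ndarray, c: np.ndarray) -> Iterator[np.ndarray]:
    """Yield every non-negative integer matrix with row sums r and column sums c.

    Depth-first allocation row by row with feasibility pruning; exponential,
    only used for small totals (see :data:`H2_EXACT_TOTAL`).
    """
    n_rows, n_cols = len(r), len(c)
    mat = np.zeros((n_rows, n_cols), dtype=np.int64)
    c_rem = np.array(c, dtype=np.int64)

    def fill_row(i: int) -> Iterator[np.ndarray]:
        if i == n_rows:
            yield mat
            return
        suffix_rows = int(np.sum(r[i + 1 :]))

        def fill_cell(j: int, rem: int) -> Iterator[np.ndarray]:
            if j == n_cols - 1:
                if rem <= c_rem[j]:
                    mat[i, j] = rem
                    c_rem[j] -= rem
                    # prune: remaining column mass must fit remaining rows
                    if c_rem.sum() == suffix_rows:
                        yield from fill_row(i + 1)
                    c_rem[j] += rem
                    mat[i, j] = 0
                return
            hi = min(rem, int(c_rem[j]))
            for v in range(hi + 1):
                mat[i, j] = v
                c_rem[j] -= v
                yield from fill_cell(j + 1, rem - v)
                c_rem[j] += v
                mat[i, j] = 0

        yield from fill_cell(0, int(r[i]))

    yield from fill_row(0)


def _h2_bounds_exact(r: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    h_min, h_max = np.inf, -np.inf
    for mat in _iter_margin_matrices(r, c):
        h = _shannon(mat)
        h_min = min(h_min, h)
        h_max = max(h_max, h)
    return h_min, h_max


def _h2_min_heuristic(r: np.ndarray, c: np.ndarray) -> float:
    """Greedy low-entropy fill: repeatedly give the largest remaining row
    margin to the largest remaining column margin (ties by original order)."""
    r_rem = r.astype(np.int64).copy()
    c_rem = c.astype(np.int64).copy()
    mat = np.zeros((len(r), len(c)), dtype=np.int64)
    while r_rem.sum() > 0:
        i = int(np.argmax(r_rem))
        j = int(np.argmax(c_rem))
        v = min(r_rem[i], c_rem[j])
        mat[i, j] += v
        r_rem[i] -= v
        c_rem[j] -= v
    return _shannon(mat)


def _h2_max_heuristic(r: np.ndarray, c: np.ndarray) -> float:
    """High-entropy fill: integer matrix as close as possible to the
    independence expectation r_i c_j / F, margins repaired exactly.

    Floor of the expected matrix, then unit increments by decreasing
    fractional remainder wherever both margins still have deficit, then a
    final greedy repair.  The result is near the entropy maximum; for small
    totals the exact enumeration path is used instead.
    """
    F = int(r.sum())
    expected = np.outer(r, c) / F
    mat = np.floor(expected).astype(np.int64)
    row_def = r - mat.sum(axis=1)
    col_def = c - mat.sum(axis=0)
    frac = expected - np.floor(expected)
    order = np.argsort(-frac, axis=None, kind="stable")
    for flat in order:
        if row_def.sum() == 0:
            break
        i, j = divmod(int(flat), len(c))
        if row_def[i] > 0 and col_def[j] > 0:
            mat[i, j] += 1
            row_def[i] -= 1
            col_def[j] -= 1
    # repair any remaining deficit (largest-remainder pass can strand units)
    while row_def.sum() > 0:
        i = int(np.argmax(row_def))
        j = int(np.argmax(col_def))
        mat[i, j] += 1
        row_def[i] -= 1
        col_def[j] -= 1
    return _shannon(mat)


def h2prime(A: LayerMatrix) -> MetricValue:
    """Complementary specialization H2' in [0, 1].

    H2' = (H2max - H2) / (H2max - H2min) where H2 is the Shannon entropy of
    the observed cell proportions and H2max/H2min are the extreme entropies
    attainable by integer matrices with the observed margins.  The bounds
    are exact (exhaustive enumeration) for small totals and heuristic fills
    otherwise; on pathological margins the heuristic bounds can be slightly
    interior to the exact ones.  Degenerate margins where H2max = H2min
    (a single attainable matrix) return 0.
    """
    _check_2x2(A, "H2'")
    r = np.asarray(A.row_margins)
    c = np.asarray(A.col_margins)
    if A.F <= H2_EXACT_TOTAL:
        h_min, h_max = _h2_bounds_exact(r, c)
        notes = "exact entropy bounds (exhaustive enumeration)"
    else:
        h_min = _h2_min_heuristic(r, c)
        h_max = _h2_max_heuristic(r, c)
        notes = "heuristic entropy bounds"
    h_obs = _shannon(A.A)
    if h_max - h_min < 1e-12:
        value = 0.0
    else:
        # heuristic bounds can be marginally interior; clamp to [0, 1]
        value = float(np.clip((h_max - h_obs) / (h_max - h_min), 0.0, 1.0))
    return MetricValue("H2", value, A.shape, notes)


# -- WNODF ------------------------------------------------------------------


def _wnodf_pairs(M: np.ndarray, margins: np.ndarray) -> float:
    """Sum of weighted-overlap contributions over ordered row pairs of M.

    Rows are assumed sorted by decreasing margin; a pair contributes only
    when the upper row's total strictly exceeds the lower's ("decreasing
    fill"), ties contribute zero.
    """
    n = M.shape[0]
    total = 0.0
    pos = M > 0
    n_pos = pos.sum(axis=1)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if margins[i] <= margins[j] or n_pos[j] == 0:
                continue
            k = int(np.count_nonzero(pos[j] & (M[j] < M[i])))
            total += 100.0 * k / int(n_pos[j])
    return total


def wnodf(A: LayerMatrix) -> MetricValue:
    """Weighted nestedness by overlap and decreasing fill, in [0, 100].

    Rows and columns are independently sorted by decreasing totals (ties
    keep the original label order and contribute zero).  For each ordered
    row pair the contribution is the percentage of the lower row's positive
    cells that are positive but strictly smaller in the upper row; column
    pairs symmetrically; the index is the mean over all row and column
    pairs.
    """
    _check_2x2(A, "WNODF")
    M = A.A.astype(float)
    r = A.row_margins
    c = A.col_margins
    row_order = np.argsort(-r, kind="stable")
    col_order = np.argsort(-c, kind="stable")
    n_p, n_a = A.shape
    total = _wnodf_pairs(M[row_order], r[row_order])
    total += _wnodf_pairs(M.T[col_order], c[col_order])
    n_pairs = n_p * (n_p - 1) // 2 + n_a * (n_a - 1) // 2
    return MetricValue("WNODF", total / n_pairs, A.shape)


# -- Morisita-Horn ----------------------------------------------------------


def morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    """Morisita-Horn overlap between two non-negative use vectors, in [0, 1].

    C = 2 sum(p_i q_i) / (sum p_i^2 + sum q_i^2) on the relative-use
    (proportion) vectors p, q.
    """
    p = np.asarray(x, dtype=float)
    q = np.asarray(y, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    return float(2.0 * (p * q).sum() / ((p * p).sum() + (q * q).sum()))


def horn_overlap(A: LayerMatrix, guild: str = "ants") -> MetricValue:
    """Mean pairwise Morisita-Horn niche overlap within one guild.

    For ants the use vectors are matrix columns (which plants each ant
    exploits, weighted by event counts); for plants, rows.  The network
    value is the unweighted mean over all guild pairs.
    """
    if guild not in ("ants", "plants"):
        raise ValueError(f"guild must be 'ants' or 'plants', got {guild!r}")
    vectors = A.A.T if guild == "ants" else A.A
    n = vectors.shape[0]
    if n < 2:
        raise UndefinedMetricError(f"Horn overlap undefined for a single {guild[:-1]}")
    vals = [
        morisita_horn(vectors[i], vectors[j])
        for i in range(n - 1)
        for j in range(i + 1, n)
    ]
    return MetricValue("Horn", float(np.mean(vals)), A.shape, f"guild={guild}")


# -- degree -----------------------------------------------------------------


def degree_centrality(A: LayerMatrix) -> dict[str, int]:
    """Binary degree (number of links) of every species in the matrix.

    A plant's degree counts its positive cells along the row; an ant's
    along the column.  Weights are ignored: degree is link count.
    """
    pos = A.A > 0
    degrees: dict[str, int] = {}
    for i, p in enumerate(A.plants):
        degrees[p] = int(pos[i].sum())
    for j, a in enumerate(A.ants):
        degrees[a] = int(pos[:, j].sum())
    return degrees
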