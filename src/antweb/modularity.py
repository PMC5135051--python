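"""Weighted bipartite modularity via simulated annealing (QuanBiMo-style).

The modularity of a partition of all species (plants and ants share one
module space) is Barber's weighted bipartite modularity

    Q = sum_ij [ a_ij/F - r_i c_j / F^2 ] * delta(module_i, module_j)

i.e. the within-module excess of interaction weight over the margin-product
expectation.  Q = 0 for the single-module partition by construction, and the
optimizer never returns anything worse than that.

``quanbimo_fit`` runs one simulated-annealing search (geometric cooling,
moves = reassign one species / merge two modules / split one module,
followed by a greedy single-species refinement); ``best_of`` repeats it with
deterministically spawned seeds and keeps the best partition, mirroring the
practice of retaining the optimum over many stochastic runs.

The annealing kernel is compiled with numba because the null-model
standardization re-fits modularity on hundreds of randomized matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from numba import njit

from .errors import UndefinedMetricError, ValidationError
from .network_model import LayerMatrix

__all__ = ["AnnealingConfig", "ModulePartition", "modularity_Q", "quanbimo_fit", "best_of"]


@dataclass(frozen=True)
class AnnealingConfig:
    """Tuning knobs of the simulated-annealing search.

    ``t0_factor`` scales the initial temperature with the matrix total F
    (T0 = t0_factor * F); ``cooling`` is the geometric factor applied once
    per sweep of S proposals (S = species count); the search stops after
    ``patience_factor * S`` proposals without improvement of the best Q.
    """

    t0_factor: float = 0.02
    cooling: float = 0.99
    patience_factor: float = 50.0
    p_merge: float = 0.10
    p_split: float = 0.05
    max_sweeps: int = 5000


@dataclass(frozen=True)
class ModulePartition:
    """A module assignment over all species of a matrix, with its Q score."""

    assignment: Mapping[str, int]
    Q: float
    n_modules: int
    seed: int
    iterations: int


def modularity_Q(A: LayerMatrix, partition: Mapping[str, int]) -> float:
    """Barber weighted bipartite modularity of a given partition.

    Every plant and ant label of the matrix must be assigned a module
    (labels are assumed unique across guilds).
    """
    missing = [s for s in (*A.plants, *A.ants) if s not in partition]
    if missing:
        raise ValidationError(f"partition does not cover species: {missing[:5]}")
    F = float(A.F)
    r = A.row_margins.astype(float)
    c = A.col_margins.astype(float)
    p_mod = np.array([partition[p] for p in A.plants])
    a_mod = np.array([partition[a] for a in A.ants])
    q = 0.0
    for m in np.unique(np.concatenate([p_mod, a_mod])):
        rows = p_mod == m
        cols = a_mod == m
        q += A.A[np.ix_(rows, cols)].sum() / F - r[rows].sum() * c[cols].sum() / F**2
    return float(q)


# -- annealing kernel -------------------------------------------------------


@njit(cache=False)
def _q_of(indptr, nbrs, wts, margin, is_plant, F, mod):  # pragma: no cover - numba
    S = margin.size
    within = 0.0
    for v in range(S):
        for e in range(indptr[v], indptr[v + 1]):
            if mod[nbrs[e]] == mod[v]:
                within += wts[e]
    within *= 0.5  # each edge stored twice
    q = within / F
    # sum over modules of Sr*Sc
    Sr = np.zeros(S)
    Sc = np.zeros(S)
    for v in range(S):
        if is_plant[v]:
            Sr[mod[v]] += margin[v]
        else:
            Sc[mod[v]] += margin[v]
    for m in range(S):
        q -= Sr[m] * Sc[m] / (F * F)
    return q


@njit(cache=False)
def _refine(indptr, nbrs, wts, margin, is_plant, F, mod, Sr, Sc, cnt):  # pragma: no cover
    """Greedy best-single-move refinement to a local optimum."""
    S = margin.size
    F2 = F * F
    cand = np.empty(S + 1, np.int64)
    for _ in range(200):
        improved = False
        for v in range(S):
            m = mod[v]
            mg = margin[v]
            # candidate targets: modules of neighbours + one empty module
            n_cand = 0
            for e in range(indptr[v], indptr[v + 1]):
                mw = mod[nbrs[e]]
                seen = False
                for t in range(n_cand):
                    if cand[t] == mw:
                        seen = True
                        break
                if not seen:
                    cand[n_cand] = mw
                    n_cand += 1
            # an empty module (fresh singleton)
            if cnt[m] > 1:
                for m2 in range(S):
                    if cnt[m2] == 0:
                        cand[n_cand] = m2
                        n_cand += 1
                        break
            w_m = 0.0
            for e in range(indptr[v], indptr[v + 1]):
                if mod[nbrs[e]] == m:
                    w_m += wts[e]
            best_dq = 1e-12
            best_m2 = -1
            best_w2 = 0.0
            for t in range(n_cand):
                m2 = cand[t]
                if m2 == m:
                    continue
                w_m2 = 0.0
                for e in range(indptr[v], indptr[v + 1]):
                    if mod[nbrs[e]] == m2:
                        w_m2 += wts[e]
                if is_plant[v]:
                    dq = (w_m2 - w_m) / F - mg * (Sc[m2] - (Sc[m] - 0.0)) / F2
                else:
                    dq = (w_m2 - w_m) / F - mg * (Sr[m2] - (Sr[m] - 0.0)) / F2
                if dq > best_dq:
                    best_dq = dq
                    best_m2 = m2
                    best_w2 = w_m2
            if best_m2 >= 0:
                mod[v] = best_m2
                cnt[m] -= 1
                cnt[best_m2] += 1
                if is_plant[v]:
                    Sr[m] -= mg
                    Sr[best_m2] += mg
                else:
                    Sc[m] -= mg
                    Sc[best_m2] += mg
                improved = True
        if not improved:
            break
    return mod


@njit(cache=False)
def _anneal(indptr, nbrs, wts, margin, is_plant, F, t0, cooling, patience,
            p_merge, p_split, max_sweeps, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    S = margin.size
    F2 = F * F
    mod = np.arange(S)
    Sr = np.zeros(S)
    Sc = np.zeros(S)
    W = np.zeros(S)
    cnt = np.ones(S, np.int64)
    for v in range(S):
        if is_plant[v]:
            Sr[v] = margin[v]
        else:
            Sc[v] = margin[v]
    q = 0.0
    best_q = 0.0
    best_mod = mod.copy()
    side = np.zeros(S, np.uint8)
    members = np.empty(S, np.int64)
    T = t0
    since = 0
    for _sweep in range(max_sweeps):
        for _p in range(S):
            u01 = np.random.random()
            if u01 < p_merge:
                # ---- merge the modules of two random nodes
                a = mod[np.int64(np.random.random() * S)]
                b = mod[np.int64(np.random.random() * S)]
                if a == b:
                    since += 1
                    continue
                w_cross = 0.0
                for v in range(S):
                    if mod[v] == a:
                        for e in range(indptr[v], indptr[v + 1]):
                            if mod[nbrs[e]] == b:
                                w_cross += wts[e]
                dq = w_cross / F - (Sr[a] * Sc[b] + Sr[b] * Sc[a]) / F2
                if dq >= 0.0 or np.random.random() < np.exp(dq / T):
                    for v in range(S):
                        if mod[v] == b:
                            mod[v] = a
                    W[a] += W[b] + w_cross
                    Sr[a] += Sr[b]
                    Sc[a] += Sc[b]
                    cnt[a] += cnt[b]
                    W[b] = 0.0
                    Sr[b] = 0.0
                    Sc[b] = 0.0
                    cnt[b] = 0
                    q += dq
            elif u01 < p_merge + p_split:
                # ---- split one module by a random bipartition
                m = mod[np.int64(np.random.random() * S)]
                if cnt[m] < 2:
                    since += 1
                    continue
                c = -1
                for m2 in range(S):
                    if cnt[m2] == 0:
                        c = m2
                        break
                if c < 0:
                    since += 1
                    continue
                n_mem = 0
                for v in range(S):
                    if mod[v] == m:
                        members[n_mem] = v
                        n_mem += 1
                n_move = 0
                for t in range(n_mem):
                    if np.random.random() < 0.5:
                        side[members[t]] = 1
                        n_move += 1
                    else:
                        side[members[t]] = 0
                if n_move == 0 or n_move == n_mem:
                    since += 1
                    continue
                sr2 = 0.0
                sc2 = 0.0
                w2 = 0.0
                w_cross = 0.0
                for t in range(n_mem):
                    v = members[t]
                    if side[v] == 1:
                        if is_plant[v]:
                            sr2 += margin[v]
                        else:
                            sc2 += margin[v]
                        for e in range(indptr[v], indptr[v + 1]):
                            u = nbrs[e]
                            if mod[u] == m:
                                if side[u] == 1:
                                    w2 += wts[e]
                                else:
                                    w_cross += wts[e]
                w2 *= 0.5
                sr1 = Sr[m] - sr2
                sc1 = Sc[m] - sc2
                dq = -w_cross / F + (sr1 * sc2 + sr2 * sc1) / F2
                if dq >= 0.0 or np.random.random() < np.exp(dq / T):
                    for t in range(n_mem):
                        v = members[t]
                        if side[v] == 1:
                            mod[v] = c
                    W[c] = w2
                    W[m] = W[m] - w2 - w_cross
                    Sr[c] = sr2
                    Sc[c] = sc2
                    Sr[m] = sr1
                    Sc[m] = sc1
                    cnt[c] = n_move
                    cnt[m] = n_mem - n_move
                    q += dq
                else:
                    for t in range(n_mem):
                        side[members[t]] = 0
            else:
                # ---- reassign one random species
                v = np.int64(np.random.random() * S)
                m = mod[v]
                if np.random.random() < 0.1:
                    m2 = -1
                    for mm in range(S):
                        if cnt[mm] == 0:
                            m2 = mm
                            break
                    if m2 < 0 or cnt[m] == 1:
                        since += 1
                        continue
                else:
                    m2 = mod[np.int64(np.random.random() * S)]
                if m2 == m:
                    since += 1
                    continue
                w_m = 0.0
                w_m2 = 0.0
                for e in range(indptr[v], indptr[v + 1]):
                    mw = mod[nbrs[e]]
                    if mw == m:
                        w_m += wts[e]
                    elif mw == m2:
                        w_m2 += wts[e]
                mg = margin[v]
                if is_plant[v]:
                    dq = (w_m2 - w_m) / F - mg * (Sc[m2] - Sc[m]) / F2
                else:
                    dq = (w_m2 - w_m) / F - mg * (Sr[m2] - Sr[m]) / F2
                if dq >= 0.0 or np.random.random() < np.exp(dq / T):
                    mod[v] = m2
                    W[m] -= w_m
                    W[m2] += w_m2
                    cnt[m] -= 1
                    cnt[m2] += 1
                    if is_plant[v]:
                        Sr[m] -= mg
                        Sr[m2] += mg
                    else:
                        Sc[m] -= mg
                        Sc[m2] += mg
                    q += dq
            if q > best_q + 1e-12:
                best_q = q
                for v in range(S):
                    best_mod[v] = mod[v]
                since = 0
            else:
                since += 1
        if since > patience:
            break
        T *= cooling
        if T < 1e-10:
            break
    # rebuild margin sums for the best state and polish it greedily
    mod = best_mod
    Sr[:] = 0.0
    Sc[:] = 0.0
    cnt[:] = 0
    for v in range(S):
        if is_plant[v]:
            Sr[mod[v]] += margin[v]
        else:
            Sc[mod[v]] += margin[v]
        cnt[mod[v]] += 1
    mod = _refine(indptr, nbrs, wts, margin, is_plant, F, mod, Sr, Sc, cnt)
    return mod, _q_of(indptr, nbrs, wts, margin, is_plant, F, mod)


def _to_csr(A: LayerMatrix):
    """Bipartite adjacency over the joint node set (plants then ants)."""
    n_p, n_a = A.shape
    S = n_p + n_a
    M = A.A
    rows, cols = np.nonzero(M)
    # duplicate each edge in both directions
    src = np.concatenate([rows, cols + n_p])
    dst = np.concatenate([cols + n_p, rows])
    w = np.concatenate([M[rows, cols], M[rows, cols]]).astype(np.float64)
    order = np.argsort(src, kind="stable")
    src, dst, w = src[order], dst[order], w[order]
    indptr = np.zeros(S + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)
    margin = np.concatenate([A.row_margins, A.col_margins]).astype(np.float64)
    is_plant = np.zeros(S, dtype=np.bool_)
    is_plant[:n_p] = True
    return indptr, dst.astype(np.int64), w, margin, is_plant


def _canonical(labels: tuple[str, ...], raw: np.ndarray) -> dict[str, int]:
    """Relabel module ids to 0..k-1 in order of first appearance."""
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for lab, m in zip(labels, raw):
        if int(m) not in remap:
            remap[int(m)] = len(remap)
        out[lab] = remap[int(m)]
    return out


def quanbimo_fit(
    A: LayerMatrix,
    config: Optional[AnnealingConfig] = None,
    seed: int = 0,
) -> ModulePartition:
    """One simulated-annealing search for a high-Q module partition.

    Stochastic but fully reproducible: the same (matrix, config, seed)
    always returns the identical partition.  The returned Q is never below
    the single-module baseline of 0.
    """
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise UndefinedMetricError("modularity undefined on a degenerate matrix")
    cfg = config or AnnealingConfig()
    indptr, nbrs, wts, margin, is_plant = _to_csr(A)
    S = margin.size
    raw, q = _anneal(
        indptr, nbrs, wts, margin, is_plant, float(A.F),
        cfg.t0_factor * A.F, cfg.cooling, cfg.patience_factor * S,
        cfg.p_merge, cfg.p_split, cfg.max_sweeps, int(seed) % (2**31 - 1),
    )
    if q < 0.0:
        raw = np.zeros(S, dtype=np.int64)
        q = 0.0
    labels = (*A.plants, *A.ants)
    assignment = _canonical(labels, raw)
    return ModulePartition(
        assignment=assignment,
        Q=float(q),
        n_modules=len(set(assignment.values())),
        seed=int(seed),
        iterations=1,
    )


def best_of(
    A: LayerMatrix,
    n_iter: int = 1000,
    config: Optional[AnnealingConfig] = None,
    seed: int = 0,
) -> ModulePartition:
    """Best partition over ``n_iter`` independently seeded annealing runs.

    Restart seeds are spawned deterministically from the master seed, so the
    result is reproducible and the optimum Q is monotone non-decreasing in
    ``n_iter`` for a fixed seed stream.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(1, 2**31 - 1, size=n_iter)
    best: Optional[ModulePartition] = None
    for s in seeds:
        fit = quanbimo_fit(A, config=config, seed=int(s))
        if best is None or fit.Q > best.Q:
            best = fit
    assert best is not None
    return ModulePartition(
        assignment=best.assignment,
        Q=best.Q,
        n_modules=best.n_modules,
        seed=int(seed),
        iterations=n_iter,
    )
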