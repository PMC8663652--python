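"""Vectorized scoring of many topologies at once.

Every unrooted binary topology on n leaves, rooted at leaf 0, reduces to a
fixed schedule of n-2 pairwise merges of state sets (Fitch) or state
intervals (Wagner).  Encoding each topology as its merge schedule lets a
whole enumeration be scored with a handful of numpy operations per merge
step, which is what makes exact search and exact-per-replicate bootstrap
fast at small taxon counts.

The scalar implementations in :mod:`morphoclad.parsimony` are the reference;
tests assert the two routes agree.
"""

from __future__ import annotations

import collections

import numpy as np

from .matrix import MISSING, CharacterMatrix, CharacterTypeSpec

_FULL_SET = (1 << 10) - 1
_LO, _HI = 0, 9


def enumerate_edge_lists(n: int) -> list[list[tuple[int, int]]]:
    """Edge lists of all unrooted binary topologies; leaves are 0..n-1."""
    from .tree import _enumerate_edge_lists

    return [list(e) for e in _enumerate_edge_lists(n)]


def merge_schedules(edge_lists: list[list[tuple[int, int]]], n: int):
    """Per-topology merge schedules rooted at leaf 0.

    Returns int arrays ``L``, ``R`` of shape (T, n-2); merge k combines
    buffer slots L[t, k] and R[t, k] into slot n+k.  Slots 0..n-1 hold leaf
    states; the final slot is the child of root leaf 0.
    """
    T = len(edge_lists)
    L = np.empty((T, n - 2), dtype=np.int64)
    R = np.empty((T, n - 2), dtype=np.int64)
    for t, edges in enumerate(edge_lists):
        adj = collections.defaultdict(list)
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        parent = {0: None}
        order = [0]
        stack = [0]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w != parent[v]:
                    parent[w] = v
                    order.append(w)
                    stack.append(w)
        slot = {v: v for v in range(n)}
        k = 0
        for v in reversed(order):
            if v >= n:
                ch = [w for w in adj[v] if w != parent[v]]
                L[t, k] = slot[ch[0]]
                R[t, k] = slot[ch[1]]
                slot[v] = n + k
                k += 1
        assert k == n - 2
    return L, R


def score_on_schedules(
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec,
    L: np.ndarray,
    R: np.ndarray,
    chunk: int = 20000,
) -> np.ndarray:
    """Unweighted per-character step counts, shape (T, n_chars).

    Rows of ``matrix`` must be in the leaf order used to build the
    schedules (leaf i = taxon i).  Only unordered and ordered modes are
    vectorized; irreversible columns are rejected here.
    """
    if any(m == "irreversible" for m in char_spec.modes):
        raise ValueError("vectorized scoring supports unordered/ordered modes only")
    n, C = matrix.n_taxa, matrix.n_chars
    T = L.shape[0]
    grid = matrix.states
    unordered_cols = np.array(
        [m == "unordered" for m in char_spec.modes], dtype=bool
    )
    S = np.zeros((T, C), dtype=np.int32)
    for start in range(0, T, chunk):
        Lc = L[start : start + chunk]
        Rc = R[start : start + chunk]
        S[start : start + chunk] = _score_chunk(grid, unordered_cols, Lc, Rc, n)
    return S


def _score_chunk(grid, unordered_cols, L, R, n) -> np.ndarray:
    T, n_merge = L.shape
    C = grid.shape[1]
    rows = np.arange(T)
    out = np.zeros((T, C), dtype=np.int32)

    # Fitch on bitmask sets
    leaf_sets = np.where(
        grid == MISSING, _FULL_SET, (1 << grid.clip(min=0).astype(np.uint16))
    ).astype(np.uint16)
    buf = np.zeros((T, n + n_merge, C), dtype=np.uint16)
    buf[:, :n, :] = leaf_sets[None, :, :]
    steps_u = np.zeros((T, C), dtype=np.int32)
    for k in range(n_merge):
        a = buf[rows, L[:, k]]
        b = buf[rows, R[:, k]]
        inter = a & b
        conflict = inter == 0
        buf[:, n + k] = np.where(conflict, a | b, inter)
        steps_u += conflict
    own = leaf_sets[0][None, :]
    steps_u += (buf[:, n + n_merge - 1] & own) == 0

    # Wagner on state intervals
    lo_leaf = np.where(grid == MISSING, _LO, grid).astype(np.int16)
    hi_leaf = np.where(grid == MISSING, _HI, grid).astype(np.int16)
    lo = np.zeros((T, n + n_merge, C), dtype=np.int16)
    hi = np.zeros((T, n + n_merge, C), dtype=np.int16)
    lo[:, :n, :] = lo_leaf[None, :, :]
    hi[:, :n, :] = hi_leaf[None, :, :]
    steps_o = np.zeros((T, C), dtype=np.int32)
    for k in range(n_merge):
        la, ha = lo[rows, L[:, k]], hi[rows, L[:, k]]
        lb, hb = lo[rows, R[:, k]], hi[rows, R[:, k]]
        nlo = np.maximum(la, lb)
        nhi = np.minimum(ha, hb)
        gap = nlo - nhi
        conflict = gap > 0
        steps_o += np.where(conflict, gap, 0)
        lo[:, n + k] = np.where(conflict, nhi, nlo)
        hi[:, n + k] = np.where(conflict, nlo, nhi)
    last_lo, last_hi = lo[:, n + n_merge - 1], hi[:, n + n_merge - 1]
    gap = np.maximum(last_lo - hi_leaf[0][None, :], lo_leaf[0][None, :] - last_hi)
    steps_o += np.where(gap > 0, gap, 0)

    out[:, unordered_cols] = steps_u[:, unordered_cols]
    out[:, ~unordered_cols] = steps_o[:, ~unordered_cols]
    return out
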