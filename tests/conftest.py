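"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's dynamic programs: lengths
are found by enumerating every internal-node state assignment and summing
per-edge costs, so they can confirm Fitch/Wagner optimizations and MPR sets
on small trees.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from morphoclad import CharacterMatrix, ParsimonyAnalysis, load_bicorniphontodes
from morphoclad.tree import Tree

LACUNA = "Bicorniphontodes_lacuna"
COMPTUS = "Bicorniphontodes_comptus"
HUYSI = "Bicorniphontodes_huysi"
HORST = "Bicorniphontodes_horstgeorgei"
CLARAE = "Bicorniphontodes_clarae"
BICORNIS = "Bicorniphontodes_bicornis"
TYPICUS = "Laophontodes_typicus"

KOREAN_TRIO = frozenset({LACUNA, COMPTUS, HUYSI})
FOUR_SPECIES = KOREAN_TRIO | {HORST}
SISTER_PAIR = frozenset({LACUNA, COMPTUS})
INGROUP = FOUR_SPECIES | {CLARAE, BICORNIS}


@pytest.fixture(scope="session")
def study():
    return load_bicorniphontodes()


@pytest.fixture(scope="session")
def study_fit(study):
    matrix, spec, outgroup = study
    return ParsimonyAnalysis(matrix, spec, outgroup).fit(method="exhaustive")


def random_matrix(
    seed: int,
    n_taxa: int = 6,
    n_chars: int = 10,
    n_states: int = 2,
    missing_p: float = 0.0,
) -> CharacterMatrix:
    """A random (not tree-generated) matrix; columns never fully missing."""
    rng = np.random.default_rng(seed)
    grid = rng.integers(0, n_states, size=(n_taxa, n_chars)).astype(int)
    if missing_p:
        mask = rng.random(grid.shape) < missing_p
        for j in range(n_chars):
            if mask[:, j].all():
                mask[rng.integers(n_taxa), j] = False
        grid = np.where(mask, -1, grid)
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], grid)


def random_column(seed: int, taxa, n_states: int = 2, missing_p: float = 0.0):
    rng = np.random.default_rng(seed)
    col = {}
    for t in taxa:
        if missing_p and rng.random() < missing_p:
            col[t] = None
        else:
            col[t] = int(rng.integers(0, n_states))
    if all(v is None for v in col.values()):
        col[min(col)] = 0
    return col


def rooted_clades(tree: Tree, outgroup: str) -> frozenset:
    """Non-trivial splits oriented as clades excluding the outgroup."""
    leaves = tree.leaves
    return frozenset(
        s if outgroup not in s else leaves - s for s in tree.bipartitions()
    )


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def _cost_fn(mode: str):
    if mode == "ordered":
        return lambda a, b: abs(a - b)
    if mode == "irreversible":
        return lambda a, b: (1 if b > a else (0 if a == b else np.inf))
    return lambda a, b: int(a != b)


def brute_force_length(tree: Tree, column: dict, mode: str = "unordered"):
    """Minimum cost over every assignment of states to internal nodes
    (and to missing tips), rooted at the smallest leaf."""
    root = min(tree.leaves)
    rv = tree.rooted_at(root)
    cost = _cost_fn(mode)
    obs = sorted({s for s in column.values() if s is not None})
    alpha = list(range(obs[0], obs[-1] + 1)) if mode == "ordered" else obs
    tips = [v for v in rv.order if not rv.children[v] or v == rv.root]
    free = [v for v in tips if column[rv.label[v]] is None]
    internals = [v for v in rv.order if rv.children[v] and v != rv.root]
    slots = internals + free
    best = np.inf
    for assign in itertools.product(alpha, repeat=len(slots)):
        state = dict(zip(slots, assign))
        for v in rv.order:
            if v in state:
                continue
            state[v] = column[rv.label[v]]
        total = 0
        for v in rv.order[1:]:
            total += cost(state[rv.parent[v]], state[v])
        best = min(best, total)
    return best


def brute_force_mpr(tree: Tree, column: dict, mode: str, outgroup: str):
    """Enumerate all optimal reconstructions with a free root node on the
    outgroup edge, keep those whose root state is the lowest among optima,
    and report per-clade state sets and per-branch (from, to) pairs."""
    rv = tree.rooted_at(outgroup)
    cost = _cost_fn(mode)
    obs = sorted({s for s in column.values() if s is not None})
    alpha = list(range(obs[0], obs[-1] + 1)) if mode == "ordered" else obs
    ROOT = -1
    (x,) = rv.children[rv.root]
    branches = [(ROOT, rv.root), (ROOT, x)]
    for v in rv.order:
        if v != rv.root:
            branches.extend((v, c) for c in rv.children[v])
    leaves = [v for v in rv.order if not rv.children[v] or v == rv.root]
    free = [v for v in leaves if column[rv.label[v]] is None]
    internals = [v for v in rv.order if rv.children[v] and v != rv.root]
    slots = [ROOT] + internals + free
    optima = []
    best = np.inf
    for assign in itertools.product(alpha, repeat=len(slots)):
        state = dict(zip(slots, assign))
        for v in leaves:
            if v not in state:
                state[v] = column[rv.label[v]]
        total = 0
        for p, c in branches:
            total += cost(state[p], state[c])
        if total < best:
            best = total
            optima = [dict(state)]
        elif total == best:
            optima.append(dict(state))
    root_pick = min(st[ROOT] for st in optima)
    optima = [st for st in optima if st[ROOT] == root_pick]
    node_sets: dict = {}
    pair_sets: dict = {}
    for st in optima:
        for p, c in branches:
            key = (
                frozenset({rv.label[rv.root]})
                if c == rv.root
                else rv.clade_leaves(c)
            )
            node_sets.setdefault(key, set()).add(st[c])
            pair_sets.setdefault(key, set()).add((st[p], st[c]))
    return best, node_sets, pair_sets
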