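"""Tree search under the parsimony criterion.

Exact methods (exhaustive enumeration and branch-and-bound) return the
complete set of minimum-length binary topologies.  The heuristic parsimony
ratchet alternates TBR hill-climbing on the original matrix and on a
perturbed matrix in which a random character sample is upweighted, which
lets the search hop between tree islands; it is fully reproducible from its
seed but, like any heuristic, only guarantees best-found length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _engine
from .matrix import CharacterMatrix, CharacterTypeSpec
from .parsimony import character_length, tree_length
from .tree import Tree, tbr_neighbors, tree_to_newick

__all__ = [
    "SearchResult",
    "exhaustive_search",
    "branch_and_bound_search",
    "ratchet_search",
]

#: Exact search is refused above this taxon count (enumeration explodes).
DEFAULT_EXACT_CAP = 9


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a parsimony tree search."""

    best_length: float
    mpts: tuple[Tree, ...]
    method: str
    evaluations: int
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mpts:
            raise ValueError("empty MPT set")

    @property
    def n_mpts(self) -> int:
        return len(self.mpts)


def _canonical_sort(trees) -> tuple[Tree, ...]:
    return tuple(sorted(set(trees), key=lambda t: tree_to_newick(t)))


def _weighted_total(S: np.ndarray, spec: CharacterTypeSpec) -> np.ndarray:
    w = np.array(
        [w if a else 0 for w, a in zip(spec.weights, spec.active)], dtype=np.int64
    )
    return S @ w


def exhaustive_search(
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    cap: int = DEFAULT_EXACT_CAP,
) -> SearchResult:
    """Score every unrooted binary topology; return the complete tie set."""
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("exact search needs at least 3 taxa")
    if n > cap:
        raise ValueError(
            f"{n} taxa exceeds the exact-search cap ({cap}); "
            "use branch_and_bound_search or ratchet_search"
        )
    labels = {i: t for i, t in enumerate(matrix.taxon_names)}
    edge_lists = _engine.enumerate_edge_lists(n)
    if any(m == "irreversible" for m in spec.modes):
        totals = np.empty(len(edge_lists), dtype=float)
        for i, edges in enumerate(edge_lists):
            t = Tree.from_edges(edges, labels)
            totals[i], _ = tree_length(t, matrix, spec, root=matrix.taxon_names[0])
    else:
        L, R = _engine.merge_schedules(edge_lists, n)
        totals = _weighted_total(_engine.score_on_schedules(matrix, spec, L, R), spec)
    best = totals.min()
    mpts = [
        Tree.from_edges(edge_lists[i], labels)
        for i in np.flatnonzero(totals == best)
    ]
    return SearchResult(
        best_length=float(best),
        mpts=_canonical_sort(mpts),
        method="exhaustive",
        evaluations=len(edge_lists),
    )


def branch_and_bound_search(
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
) -> SearchResult:
    """Exact search by stepwise taxon addition with length-bound pruning.

    A partial topology's length never decreases when a taxon is inserted, so
    any partial tree already longer than the best complete length found can
    be discarded with its whole subtree of completions.
    """
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    names = matrix.taxon_names
    n = matrix.n_taxa
    if n < 4:
        return exhaustive_search(matrix, spec, cap=max(DEFAULT_EXACT_CAP, n))
    state = {"best": np.inf, "mpts": [], "evals": 0}
    labels_all = {i: t for i, t in enumerate(names)}

    def partial_length(edges, k) -> float:
        t = Tree.from_edges(edges, {i: names[i] for i in range(k)})
        total = 0.0
        for j in range(matrix.n_chars):
            if not spec.active[j]:
                continue
            col = {names[i]: matrix.column(j)[names[i]] for i in range(k)}
            total += spec.weights[j] * character_length(
                t, col, spec.modes[j], root=names[0]
            )
        return total

    def recurse(edges, k, nxt):
        state["evals"] += 1
        length = partial_length(edges, k)
        if length > state["best"]:
            return
        if k == n:
            if length < state["best"]:
                state["best"] = length
                state["mpts"] = [list(edges)]
            elif length == state["best"]:
                state["mpts"].append(list(edges))
            return
        for i in range(len(edges)):
            a, b = edges[i]
            recurse(
                edges[:i] + edges[i + 1 :] + [(a, nxt), (b, nxt), (k, nxt)],
                k + 1,
                nxt + 1,
            )

    recurse([(0, n), (1, n), (2, n)], 3, n + 1)
    mpts = [Tree.from_edges(e, labels_all) for e in state["mpts"]]
    return SearchResult(
        best_length=float(state["best"]),
        mpts=_canonical_sort(mpts),
        method="branch_and_bound",
        evaluations=state["evals"],
    )


# ---------------------------------------------------------------------------
# Parsimony ratchet
# ---------------------------------------------------------------------------

def _stepwise_addition(
    matrix: CharacterMatrix, spec: CharacterTypeSpec, order: Sequence[int]
) -> Tree:
    """Greedy stepwise addition following ``order`` (taxon row indices)."""
    names = matrix.taxon_names
    edges = [(order[0], -1), (order[1], -1), (order[2], -1)]
    nxt = -2
    placed = list(order[:3])
    for k in order[3:]:
        placed.append(k)
        best_len, best_edges = None, None
        for i in range(len(edges)):
            a, b = edges[i]
            cand = edges[:i] + edges[i + 1 :] + [(a, nxt), (b, nxt), (k, nxt)]
            t = Tree.from_edges(cand, {j: names[j] for j in placed})
            total = _length_on(t, matrix, spec, placed)
            if best_len is None or total < best_len:
                best_len, best_edges = total, cand
        edges = best_edges
        nxt -= 1
    return Tree.from_edges(edges, {j: names[j] for j in placed})


def _length_on(tree: Tree, matrix, spec, rows=None) -> float:
    from .parsimony import _fitch_length, _wagner_length

    names = matrix.taxon_names
    rows = list(range(matrix.n_taxa) if rows is None else rows)
    present = [names[i] for i in rows]
    rv = tree.rooted_at(min(present))
    total = 0.0
    for j in range(matrix.n_chars):
        if not spec.active[j]:
            continue
        colfull = matrix.column(j)
        col = {t: colfull[t] for t in present}
        mode = spec.modes[j]
        if mode == "ordered":
            s = _wagner_length(rv, col)
        elif mode == "unordered":
            s = _fitch_length(rv, col)
        else:
            s = character_length(tree, col, mode, root=min(present))
        total += spec.weights[j] * s
    return total


def _tbr_climb(
    tree: Tree, matrix, spec, hold: int, counter: dict
) -> tuple[float, list[Tree]]:
    """First-descent TBR hill climb; on a plateau collect up to ``hold``
    equally good trees (the input included)."""
    current = tree
    cur_len = _length_on(current, matrix, spec)
    counter["evals"] += 1
    improved = True
    while improved:
        improved = False
        for nb in tbr_neighbors(current):
            counter["evals"] += 1
            ln = _length_on(nb, matrix, spec)
            if ln < cur_len:
                current, cur_len = nb, ln
                improved = True
                break
    held = [current]
    for nb in tbr_neighbors(current):
        if len(held) >= hold:
            break
        counter["evals"] += 1
        if _length_on(nb, matrix, spec) == cur_len and nb not in held:
            held.append(nb)
    return cur_len, held


def ratchet_search(
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    iterations: int = 1000,
    trees_to_hold: int = 5,
    characters_to_sample: int = 10,
    random_constraint_level: int = 10,
    seed: int = 0,
) -> SearchResult:
    """Parsimony ratchet: alternating reweighted and original TBR climbs.

    ``random_constraint_level`` is taken as the number of random-addition
    starting trees.  Perturbation doubles the weight of
    ``characters_to_sample`` randomly chosen characters.  With
    ``iterations=0`` the stepwise-addition starting trees are returned
    unimproved.
    """
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    if characters_to_sample > matrix.n_chars:
        raise ValueError("characters_to_sample exceeds the character count")
    rng = np.random.default_rng(seed)
    counter = {"evals": 0}
    best_len = np.inf
    best_set: list[Tree] = []

    def consider(length, trees):
        nonlocal best_len, best_set
        if length < best_len:
            best_len = length
            best_set = list(trees)
        elif length == best_len:
            for t in trees:
                if t not in best_set:
                    best_set.append(t)

    n = matrix.n_taxa
    for _ in range(max(1, random_constraint_level)):
        order = list(rng.permutation(n))
        start = _stepwise_addition(matrix, spec, order)
        if iterations == 0:
            consider(_length_on(start, matrix, spec), [start])
            continue
        cur_len, held = _tbr_climb(start, matrix, spec, trees_to_hold, counter)
        consider(cur_len, held)
        current = held[0]
        for _it in range(iterations):
            sample = rng.choice(
                matrix.n_chars, size=characters_to_sample, replace=False
            )
            bumped = list(spec.weights)
            for j in sample:
                bumped[int(j)] += 1
            pert = CharacterTypeSpec(
                modes=spec.modes, weights=tuple(bumped), active=spec.active
            )
            _, held_p = _tbr_climb(current, matrix, pert, 1, counter)
            cur_len, held = _tbr_climb(
                held_p[0], matrix, spec, trees_to_hold, counter
            )
            consider(cur_len, held)
            current = held[0]
    return SearchResult(
        best_length=float(best_len),
        mpts=_canonical_sort(best_set),
        method="ratchet",
        evaluations=counter["evals"],
        seed=seed,
        settings={
            "iterations": iterations,
            "trees_to_hold": trees_to_hold,
            "characters_to_sample": characters_to_sample,
            "random_constraint_level": random_constraint_level,
        },
    )
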