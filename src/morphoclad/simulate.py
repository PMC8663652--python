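"""Synthetic character matrices evolved on known trees.

The generator emulates morphological matrices of the bundled study's kind:
binary or three-state characters on a small taxon set, evolved down a known
topology either symmetrically (``mk_unordered``) or under irreversible
stepwise gain (``irreversible_gain``, the oligomerization premise: derived
states accumulate and are never lost), with tunable expected change count
per character and a missing-data mask.  It exists so that search, mapping
and support machinery can be tested end to end against a known truth.

Homoplasy is controlled through the rate: the expected number of change
events per character on the whole tree.  Events in excess of one per
character create convergence or reversal; under ``irreversible_gain`` a
character that changed at most once is perfectly compatible with the
generating tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .tree import Tree

__all__ = ["SimulationConfig", "simulate_yule_tree", "simulate_characters"]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for :func:`simulate_characters`.

    ``rate`` is the expected number of change events per character on the
    whole tree; ``missing_fraction`` of entries are masked to ``?`` after
    simulation.
    """

    n_chars: int
    n_states: int = 2
    model: str = "mk_unordered"
    rate: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0
    drop_constant: bool = False

    def __post_init__(self):
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if self.model not in ("mk_unordered", "irreversible_gain"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not 0.0 <= self.missing_fraction <= 0.5:
            raise ValueError("missing_fraction must be in [0, 0.5]")


def simulate_yule_tree(n_taxa: int, seed: int = 0, prefix: str = "t") -> Tree:
    """A uniformly random unrooted binary topology on ``n_taxa`` leaves.

    Built by sequential attachment: taxon k joins a uniformly chosen edge of
    the partial tree, which yields each of the (2n-5)!! topologies with
    equal probability.  Deterministic per seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    n = n_taxa
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for leaf in range(3, n):
        i = int(rng.integers(len(edges)))
        a, b = edges.pop(i)
        edges += [(a, nxt), (b, nxt), (leaf, nxt)]
        nxt += 1
    labels = {i: f"{prefix}{i + 1}" for i in range(n)}
    return Tree.from_edges(edges, labels)


def simulate_characters(
    tree: Tree, config: SimulationConfig, return_internal: bool = False
):
    """Evolve characters independently down ``tree``.

    Evolution is rooted at the internal node adjacent to the alphabetically
    first leaf, with root state 0 (the plesiomorphic condition).  Each
    character receives a Poisson(rate) number of change events placed
    uniformly on the branches; an event replaces the current state by a
    uniformly chosen different state (``mk_unordered``) or increments it by
    one step up to the top state (``irreversible_gain``; events at the top
    state are silent).

    Returns the (masked) matrix and the latent unmasked tip-state grid, so
    callers can assert generative properties that masking would hide; with
    ``return_internal=True`` a third value maps each node's clade leaf set
    to its latent states, exposing the full generative history.
    """
    if not tree.is_binary:
        raise ValueError("simulation requires a binary tree")
    rng = np.random.default_rng(config.seed)
    taxa = sorted(tree.leaves)
    rv = tree.rooted_at(taxa[0])
    # evolve from the node adjacent to the root leaf so every tip, including
    # the first taxon, lies below at least one branch
    (top,) = rv.children[rv.root]
    branches = [(rv.parent[v], v) for v in rv.order if v != rv.root and v != top]
    branches.append((top, rv.root))  # pendant branch to the first taxon
    n_br = len(branches)
    order_index = {b: i for i, b in enumerate(branches)}

    n_taxa = len(taxa)
    latent = np.zeros((n_taxa, config.n_chars), dtype=np.int8)
    taxon_row = {t: i for i, t in enumerate(taxa)}
    node_states: dict[int, list[int]] = {v: [] for v in rv.order}

    for j in range(config.n_chars):
        k = int(rng.poisson(config.rate))
        hits = rng.integers(0, n_br, size=k) if k else np.array([], dtype=int)
        per_branch = np.bincount(hits, minlength=n_br)
        state: dict[int, int] = {top: 0}
        _apply = _event_mk if config.model == "mk_unordered" else _event_gain
        # walk branches parent-before-child; the stem to the root leaf last
        for b, (p, c) in enumerate(branches):
            s = state[p]
            for _ in range(int(per_branch[b])):
                s = _apply(s, config.n_states, rng)
            state[c] = s
        for v in rv.order:
            node_states[v].append(state[v])
            if not rv.children[v] or v == rv.root:
                latent[taxon_row[rv.label[v]], j] = state[v]

    grid = latent.copy()
    if config.missing_fraction > 0:
        mask = rng.random(grid.shape) < config.missing_fraction
        # never mask out a whole column
        for j in range(config.n_chars):
            if mask[:, j].all():
                mask[int(rng.integers(n_taxa)), j] = False
        grid = np.where(mask, MISSING, grid)
    if config.drop_constant:
        keep = [
            j
            for j in range(config.n_chars)
            if len({s for s in grid[:, j] if s != MISSING}) > 1
        ]
        if keep:
            grid = grid[:, keep]
            latent = latent[:, keep]
            node_states = {v: [s[j] for j in keep] for v, s in node_states.items()}
    matrix = CharacterMatrix(taxa, grid)
    if return_internal:
        clade_states = {
            (rv.clade_leaves(v) if v != rv.root else frozenset({rv.label[rv.root]})):
                np.array(s, dtype=np.int8)
            for v, s in node_states.items()
        }
        return matrix, latent, clade_states
    return matrix, latent


def _event_mk(state: int, n_states: int, rng) -> int:
    step = int(rng.integers(1, n_states))
    return (state + step) % n_states


def _event_gain(state: int, n_states: int, rng) -> int:
    return min(state + 1, n_states - 1)
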