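"""Nonparametric bootstrap clade support.

Each replicate resamples the characters with replacement, finds that
replicate's most parsimonious trees, summarizes them by strict consensus,
and scores every clade (outgroup-rooted leaf set) present in the consensus.
Support is the percentage of replicates containing the clade.  Counting via
the strict consensus is conservative: a clade counts only when it is
unambiguous among the replicate's optimal trees; ``count_in_any_mpt=True``
switches to crediting a clade found in at least one optimal tree.

For matrices small enough for exact search the per-replicate search scores
the full enumeration.  Because parsimony length is additive over characters,
resampling only reweights the per-topology/per-character step matrix, so
the enumeration is scored once and each replicate reduces to one matrix
product -- exactly equivalent to running exhaustive search per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .matrix import CharacterMatrix, CharacterTypeSpec
from .search import DEFAULT_EXACT_CAP, _stepwise_addition, _tbr_climb
from .tree import Tree

__all__ = ["CladeSupportTable", "bootstrap_support"]


@dataclass(frozen=True)
class CladeSupportTable:
    """Bootstrap clade frequencies in percent, outgroup-rooted."""

    frequencies: dict[frozenset[str], float]
    replications: int
    outgroup: str
    seed: int | None
    settings: dict = field(default_factory=dict)

    def percent(self, clade) -> float:
        """Support for a clade given as an iterable of ingroup leaf labels."""
        return self.frequencies.get(frozenset(clade), 0.0)

    def rounded(self) -> dict[frozenset[str], int]:
        return {c: int(round(v)) for c, v in self.frequencies.items()}

    def to_rows(self):
        for clade, pct in sorted(
            self.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        ):
            yield ",".join(sorted(clade)), pct


def _rooted_clades(splits, leaves: frozenset, outgroup: str):
    """Orient unrooted splits as clades excluding the outgroup; the full
    ingroup clade (trivial split on the outgroup pendant edge) is always
    present under outgroup rooting and is included by convention."""
    clades = {frozenset(leaves - {outgroup})}
    for s in splits:
        clades.add(s if outgroup not in s else leaves - s)
    return clades


def bootstrap_support(
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    outgroup: str | None = None,
    replications: int = 500,
    searches_per_replicate: int = 10,
    max_trees: int = 100,
    seed: int = 0,
    search_mode: str = "auto",
    count_in_any_mpt: bool = False,
) -> CladeSupportTable:
    """Bootstrap clade support table.

    ``search_mode``: ``"exact"`` (full enumeration per replicate, taxon count
    permitting), ``"tbr"`` (random-addition starts plus TBR climbing,
    ``searches_per_replicate`` restarts holding up to ``max_trees`` trees),
    or ``"auto"`` to pick exact when feasible.
    """
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    outgroup = outgroup if outgroup is not None else matrix.taxon_names[0]
    if outgroup not in matrix.taxon_names:
        raise KeyError(f"outgroup {outgroup!r} not in matrix")
    if replications < 1:
        raise ValueError("replications must be positive")
    if search_mode == "auto":
        search_mode = "exact" if matrix.n_taxa <= DEFAULT_EXACT_CAP else "tbr"
    rng = np.random.default_rng(seed)
    leaves = frozenset(matrix.taxon_names)
    counts = rng.multinomial(
        matrix.n_chars, [1.0 / matrix.n_chars] * matrix.n_chars, size=replications
    )
    if search_mode == "exact":
        tallies = _exact_replicates(matrix, spec, outgroup, counts, count_in_any_mpt)
    elif search_mode == "tbr":
        tallies = _tbr_replicates(
            matrix, spec, outgroup, counts, searches_per_replicate, max_trees,
            rng, count_in_any_mpt,
        )
    else:
        raise ValueError(f"unknown search_mode {search_mode!r}")
    freqs = {c: 100.0 * k / replications for c, k in tallies.items()}
    return CladeSupportTable(
        frequencies=freqs,
        replications=replications,
        outgroup=outgroup,
        seed=seed,
        settings={
            "search_mode": search_mode,
            "searches_per_replicate": searches_per_replicate,
            "max_trees": max_trees,
            "count_in_any_mpt": count_in_any_mpt,
        },
    )


def _exact_replicates(matrix, spec, outgroup, counts, any_mpt):
    n = matrix.n_taxa
    labels = {i: t for i, t in enumerate(matrix.taxon_names)}
    edge_lists = _engine.enumerate_edge_lists(n)
    L, R = _engine.merge_schedules(edge_lists, n)
    S = _engine.score_on_schedules(matrix, spec, L, R)
    w = np.array(
        [w if a else 0 for w, a in zip(spec.weights, spec.active)], dtype=np.int64
    )
    Sw = S * w[None, :]
    leaves = frozenset(matrix.taxon_names)
    split_cache: list[frozenset | None] = [None] * len(edge_lists)

    def splits_of(i):
        if split_cache[i] is None:
            split_cache[i] = Tree.from_edges(edge_lists[i], labels).bipartitions()
        return split_cache[i]

    tallies: dict[frozenset, int] = {}
    for row in counts:
        lengths = Sw @ row
        ties = np.flatnonzero(lengths == lengths.min())
        if any_mpt:
            agg = frozenset().union(*(splits_of(i) for i in ties))
        else:
            agg = splits_of(ties[0])
            for i in ties[1:]:
                agg = agg & splits_of(i)
        for clade in _rooted_clades(agg, leaves, outgroup):
            tallies[clade] = tallies.get(clade, 0) + 1
    return tallies


def _tbr_replicates(
    matrix, spec, outgroup, counts, searches, max_trees, rng, any_mpt
):
    leaves = frozenset(matrix.taxon_names)
    tallies: dict[frozenset, int] = {}
    n = matrix.n_taxa
    for row in counts:
        # resampling == reweighting: a character drawn c times gets weight c*w
        rep_spec = CharacterTypeSpec(
            modes=spec.modes,
            weights=tuple(
                max(1, int(w * c)) for w, c in zip(spec.weights, row)
            ),
            active=tuple(a and c > 0 for a, c in zip(spec.active, row)),
        )
        best_len: float = np.inf
        best: list = []
        counter = {"evals": 0}
        for _ in range(max(1, searches)):
            order = list(rng.permutation(n))
            start = _stepwise_addition(matrix, rep_spec, order)
            ln, held = _tbr_climb(start, matrix, rep_spec, max_trees, counter)
            if ln < best_len:
                best_len, best = ln, list(held)
            elif ln == best_len:
                for t in held:
                    if t not in best and len(best) < max_trees:
                        best.append(t)
        if not best:
            continue  # unresolved replicate contributes to no clade
        if any_mpt:
            agg = frozenset().union(*(t.bipartitions() for t in best))
        else:
            agg = best[0].bipartitions()
            for t in best[1:]:
                agg = agg & t.bipartitions()
        for clade in _rooted_clades(agg, leaves, outgroup):
            tallies[clade] = tallies.get(clade, 0) + 1
    return tallies
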