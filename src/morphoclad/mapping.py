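"""Ancestral-state mapping and synapomorphy/homoplasy classification.

A change is *unambiguous* when every most-parsimonious reconstruction (MPR)
of the character places a change on the same branch with the same from/to
states -- the intersection of all MPRs, which is what tree-drawing programs
plot when asked for unambiguous changes only.

The tree is evaluated rooted on the outgroup's pendant edge.  The root node
carries no fixed state: the outgroup's observed state enters as data, so
reversals toward state 0 can be recovered as derived changes on ingroup
branches.  When the root state itself is ambiguous among MPRs, the tie is
resolved toward the lowest state, i.e. the presumed plesiomorphic condition
of the 0-based coding; this is what keeps a state found only in the
outgroup an outgroup autapomorphy rather than an apparent ingroup loss.

Classification follows the per-character consistency index on the tree: a
character that fits perfectly (ci = 1) yields synapomorphies on internal
branches and autapomorphies on pendant branches; a character with ci < 1 is
homoplastic and its changes are flagged as such wherever they fall.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import CharacterMatrix, CharacterTypeSpec
from .parsimony import min_steps
from .tree import RootedView, Tree

__all__ = [
    "ChangeRecord",
    "mpr_state_sets",
    "unambiguous_changes",
    "shared_changes_across_mpts",
]


@dataclass(frozen=True)
class ChangeRecord:
    """One unambiguous state transition on a branch.

    The branch is identified by the leaf set of the clade below it in the
    outgroup-rooted view, which keeps records comparable across topologies.
    """

    clade: frozenset[str]
    character: int
    from_state: int
    to_state: int
    classification: str  # synapomorphy | autapomorphy | homoplasy
    scope: str = "tree"  # tree | all_mpts

    def sort_key(self):
        return (len(self.clade), sorted(self.clade), self.character)


def _mode_cost(mode: str):
    if mode == "ordered":
        return lambda a, b: abs(a - b)
    return lambda a, b: int(a != b)


def _alphabet(column: dict, mode: str) -> list[int]:
    obs = sorted({s for s in column.values() if s is not None})
    if mode == "ordered":
        return list(range(obs[0], obs[-1] + 1))
    return obs


class _RootedMPR:
    """Sankoff down-pass plus top-down MPR reachability on one character.

    The evaluation tree is the input tree with a root node subdividing the
    pendant edge of ``root_label``; that leaf and the rest of the tree are
    the root's two children.
    """

    ROOT = -1  # synthetic root node id (leaf/internal ids are >= 0)

    def __init__(self, rv: RootedView, column: dict, mode: str):
        self.rv = rv
        self.column = column
        self.alpha = _alphabet(column, mode)
        self.cost = _mode_cost(mode)
        self._down_pass()
        self._reach_pass()

    def _down_pass(self):
        rv, col, alpha, cost = self.rv, self.column, self.alpha, self.cost
        INF = float("inf")
        down: dict[int, dict[int, float]] = {}
        for v in rv.postorder():
            if v == rv.root:
                continue
            ch = rv.children[v]
            if not ch:
                s = col[rv.label[v]]
                down[v] = {a: (0.0 if s is None or a == s else INF) for a in alpha}
            else:
                down[v] = {
                    a: sum(
                        min(down[c][t] + cost(a, t) for t in alpha) for c in ch
                    )
                    for a in alpha
                }
        s = col[rv.label[rv.root]]
        down[rv.root] = {a: (0.0 if s is None or a == s else INF) for a in alpha}
        (x,) = self.rv.children[self.rv.root]
        down[self.ROOT] = {
            a: min(down[rv.root][t] + cost(a, t) for t in alpha)
            + min(down[x][t] + cost(a, t) for t in alpha)
            for a in alpha
        }
        self.down = down
        self.length = min(down[self.ROOT].values())

    def _reach_pass(self):
        rv, alpha, cost, down = self.rv, self.alpha, self.cost, self.down
        best = min(down[self.ROOT].values())
        root_set = {a for a in alpha if down[self.ROOT][a] == best}
        # plesiomorphy-biased resolution of a root-state tie
        reach: dict[int, set[int]] = {self.ROOT: {min(root_set)}}
        self.root_mpr_set = root_set
        pairs: dict[tuple[int, int], set[tuple[int, int]]] = {}
        (x,) = rv.children[rv.root]
        branches = [(self.ROOT, rv.root), (self.ROOT, x)]
        for v in rv.order:
            if v in (rv.root,):
                continue
            branches.extend((v, c) for c in rv.children[v])
        for p, c in branches:
            rc: set[int] = set()
            pc: set[tuple[int, int]] = set()
            for s in reach[p]:
                m = min(down[c][t] + cost(s, t) for t in alpha)
                for t in alpha:
                    if down[c][t] + cost(s, t) == m:
                        rc.add(t)
                        pc.add((s, t))
            reach[c] = rc
            pairs[(p, c)] = pc
        self.reach = reach
        self.pairs = pairs
        self.branches = branches

    def branch_clade(self, child: int) -> frozenset[str]:
        rv = self.rv
        if child == rv.root:
            return frozenset({rv.label[rv.root]})
        return rv.clade_leaves(child)


def mpr_state_sets(
    tree: Tree, column, mode: str = "unordered", root: str | None = None
) -> dict[frozenset[str], set[int]]:
    """States assignable to each node in at least one MPR.

    Keys are clade leaf sets of the view rooted on the pendant edge of
    ``root`` (default: the smallest leaf label); the full leaf set keys the
    root node after the plesiomorphy tie-break.  Missing tips carry the
    full alphabet.
    """
    root_label = root if root is not None else min(tree.leaves)
    rv = tree.rooted_at(root_label)
    col = column if isinstance(column, dict) else dict(zip(sorted(tree.leaves), column))
    mpr = _RootedMPR(rv, col, mode)
    out: dict[frozenset[str], set[int]] = {}
    for v, states in mpr.reach.items():
        if v == mpr.ROOT:
            out[frozenset(tree.leaves)] = set(states)
        else:
            out[mpr.branch_clade(v)] = set(states)
    return out


def unambiguous_changes(
    tree: Tree,
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    outgroup: str | None = None,
) -> list[ChangeRecord]:
    """All changes placed identically (branch, from, to) by every MPR."""
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    root_label = outgroup if outgroup is not None else min(tree.leaves)
    rv = tree.rooted_at(root_label)
    records: list[ChangeRecord] = []
    for j in range(matrix.n_chars):
        if not spec.active[j]:
            continue
        col = matrix.column(j)
        obs = {s for s in col.values() if s is not None}
        if len(obs) <= 1:
            continue
        mode = spec.modes[j]
        map_mode = "ordered" if mode == "ordered" else "unordered"
        mpr = _RootedMPR(rv, col, map_mode)
        homoplastic = min_steps(col, map_mode) < mpr.length
        for (p, c), pc in mpr.pairs.items():
            changed = {(a, b) for a, b in pc if a != b}
            if changed != pc or len(changed) != 1:
                continue  # no change, or placement/identity varies over MPRs
            ((a, b),) = changed
            clade = mpr.branch_clade(c)
            if homoplastic:
                cls = "homoplasy"
            elif len(clade) == 1:
                cls = "autapomorphy"
            else:
                cls = "synapomorphy"
            records.append(ChangeRecord(clade, j, a, b, cls))
    records.sort(key=ChangeRecord.sort_key)
    return records


def shared_changes_across_mpts(
    mpts,
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    outgroup: str | None = None,
) -> list[ChangeRecord]:
    """Unambiguous changes present in every tree of an MPT set.

    Records are matched on (clade leaf set, character, from, to), so the
    intersection is well defined across topologies that resolve other parts
    of the tree differently.
    """
    mpts = list(mpts)
    if not mpts:
        raise ValueError("empty MPT set")
    per_tree = [
        {
            (r.clade, r.character, r.from_state, r.to_state): r
            for r in unambiguous_changes(t, matrix, char_spec, outgroup)
        }
        for t in mpts
    ]
    shared = set(per_tree[0])
    for d in per_tree[1:]:
        shared &= set(d)
    out = [
        ChangeRecord(
            r.clade, r.character, r.from_state, r.to_state, r.classification,
            scope="all_mpts",
        )
        for key, r in per_tree[0].items()
        if key in shared
    ]
    out.sort(key=ChangeRecord.sort_key)
    return out
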