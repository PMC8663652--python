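"""Unrooted tree topologies for parsimony analysis.

Trees carry no branch lengths: a :class:`Tree` is a leaf-labelled unrooted
topology, fully resolved (internal degree 3) or partially collapsed after
consensus.  Identity is canonical: two trees are equal iff they induce the
same set of bipartitions of the same leaf set.  Rooting on an outgroup is a
view used for clade language, Newick output and character mapping; it never
changes identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Tree",
    "RootedView",
    "enumerate_unrooted_topologies",
    "count_unrooted_topologies",
    "tbr_neighbors",
    "nni_neighbors",
    "strict_consensus",
    "tree_from_bipartitions",
    "tree_to_newick",
    "tree_from_newick",
]


@dataclass(frozen=True)
class RootedView:
    """A rooted traversal of a tree: the root is a designated leaf.

    ``order`` lists nodes parent-before-child starting at the root leaf;
    ``children``/``parent`` describe the induced directed tree; ``label``
    maps leaf node ids to taxon labels.
    """

    root: int
    order: tuple[int, ...]
    parent: dict[int, int | None]
    children: dict[int, tuple[int, ...]]
    label: dict[int, str]

    def clade_leaves(self, node: int) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            ch = self.children[v]
            if not ch:
                out.append(self.label[v])
            stack.extend(ch)
        return frozenset(out)

    def postorder(self) -> Iterator[int]:
        return reversed(self.order)


class Tree:
    """Unrooted leaf-labelled topology with canonical (bipartition) identity."""

    __slots__ = ("_adj", "_labels", "_leafset", "_splits")

    def __init__(self, adj: Mapping[int, Iterable[int]], labels: Mapping[int, str]):
        self._adj = {v: frozenset(ns) for v, ns in adj.items()}
        self._labels = dict(labels)
        for v, ns in self._adj.items():
            deg = len(ns)
            if v in self._labels:
                if deg not in (0, 1):
                    raise ValueError(f"leaf node {v} has degree {deg}")
            elif deg == 2:
                raise ValueError(f"internal node {v} has degree 2")
            elif deg < 3 and len(self._adj) > 1:
                raise ValueError(f"internal node {v} has degree {deg}")
        if len(set(self._labels.values())) != len(self._labels):
            raise ValueError("duplicate leaf labels")
        self._leafset = frozenset(self._labels.values())
        self._splits: frozenset[frozenset[str]] | None = None

    # -- basic accessors ----------------------------------------------------

    @property
    def leaves(self) -> frozenset[str]:
        return self._leafset

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def edges(self) -> Iterator[tuple[int, int]]:
        for v, ns in self._adj.items():
            for w in ns:
                if v < w:
                    yield (v, w)

    @property
    def is_binary(self) -> bool:
        return all(
            len(ns) == 3 for v, ns in self._adj.items() if v not in self._labels
        )

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[int, int]], labels: Mapping[int, str]
    ) -> "Tree":
        adj: dict[int, set[int]] = {}
        for a, b in edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for v in labels:
            adj.setdefault(v, set())
        return cls(adj, labels)

    @classmethod
    def star(cls, labels: Sequence[str]) -> "Tree":
        """The fully unresolved tree on ``labels``."""
        n = len(labels)
        return cls.from_edges(
            [(i, n) for i in range(n)], {i: t for i, t in enumerate(labels)}
        )

    # -- identity -----------------------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each stored as the block excluding the
        lexicographically smallest leaf label."""
        if self._splits is None:
            ref = min(self._leafset)
            out = set()
            for a, b in self.edges():
                side = self._component_leaves(b, a)
                if ref in side:
                    side = self._leafset - side
                if 1 < len(side) < self.n_leaves - 1:
                    out.add(frozenset(side))
            self._splits = frozenset(out)
        return self._splits

    def _component_leaves(self, start: int, blocked: int) -> set[str]:
        seen = {blocked, start}
        out = []
        stack = [start]
        while stack:
            v = stack.pop()
            if v in self._labels:
                out.append(self._labels[v])
            for w in self._adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return set(out)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Tree)
            and self._leafset == other._leafset
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self) -> int:
        return hash((self._leafset, self.bipartitions()))

    def __repr__(self) -> str:
        return f"<Tree on {self.n_leaves} leaves: {tree_to_newick(self).strip()}>"

    # -- rooting ------------------------------------------------------------

    def rooted_at(self, leaf_label: str) -> RootedView:
        """Root the tree at the named leaf (outgroup rooting).

        The leaf itself becomes the root so its observed state polarizes the
        stem branch to the rest of the tree.
        """
        root = self._node_of(leaf_label)
        parent: dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            v = stack.pop()
            for w in self._adj[v]:
                if w != parent[v]:
                    parent[w] = v
                    order.append(w)
                    stack.append(w)
        children: dict[int, tuple[int, ...]] = {v: () for v in order}
        for v in order[1:]:
            children[parent[v]] = children[parent[v]] + (v,)
        return RootedView(root, tuple(order), parent, children, dict(self._labels))

    def root_on_outgroup(self, outgroup: str) -> RootedView:
        """Alias for :meth:`rooted_at`; rooting is idempotent by construction."""
        return self.rooted_at(outgroup)

    def _node_of(self, label: str) -> int:
        for v, lab in self._labels.items():
            if lab == label:
                return v
        raise KeyError(f"no leaf labelled {label!r}")

    def relabelled(self, mapping: Mapping[str, str]) -> "Tree":
        return Tree(self._adj, {v: mapping[l] for v, l in self._labels.items()})


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def count_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labelled leaves."""
    if n < 3:
        raise ValueError("need at least 3 leaves")
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def enumerate_unrooted_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology on ``taxa`` exactly once.

    Generation is by sequential insertion: taxon k is attached to each of the
    2k-5 edges of every partial tree, which produces each topology once.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    labels = {i: t for i, t in enumerate(taxa)}
    for edges in _enumerate_edge_lists(n):
        yield Tree.from_edges(edges, labels)


def _enumerate_edge_lists(n: int) -> Iterator[list[tuple[int, int]]]:
    """Edge lists over nodes 0..2n-3 with leaves 0..n-1 (internal from n)."""
    base = [(0, n), (1, n), (2, n)]

    def rec(edges: list[tuple[int, int]], leaf: int, nxt: int):
        if leaf == n:
            yield edges
            return
        for i in range(len(edges)):
            a, b = edges[i]
            yield from rec(
                edges[:i] + edges[i + 1 :] + [(a, nxt), (b, nxt), (leaf, nxt)],
                leaf + 1,
                nxt + 1,
            )

    yield from rec(base, 3, n + 1)


# ---------------------------------------------------------------------------
# Rearrangements
# ---------------------------------------------------------------------------

def _suppress_degree_two(adj: dict[int, set[int]], labels: Mapping[int, str]) -> None:
    for v in list(adj):
        if v not in labels and len(adj[v]) == 2:
            a, b = adj[v]
            adj[a].discard(v)
            adj[b].discard(v)
            adj[a].add(b)
            adj[b].add(a)
            del adj[v]


def tbr_neighbors(tree: Tree) -> Iterator[Tree]:
    """All distinct topologies one tree-bisection-reconnection move away.

    Every edge is bisected; the two fragments are reconnected by joining any
    edge of one to any edge of the other.  The input topology itself is not
    yielded.
    """
    if not tree.is_binary or tree.n_leaves < 4:
        raise ValueError("TBR requires a binary tree with >= 4 leaves")
    labels = tree._labels
    seen: set[Tree] = {tree}
    base_adj = {v: set(ns) for v, ns in tree._adj.items()}
    nxt_id = max(base_adj) + 1
    for u, v in list(tree.edges()):
        adj = {x: set(ns) for x, ns in base_adj.items()}
        adj[u].discard(v)
        adj[v].discard(u)
        u_side = (base_adj[u] - {v}) | {u}
        v_side = (base_adj[v] - {u}) | {v}
        _suppress_degree_two(adj, labels)
        # suppression may have removed u or v themselves
        rep_u = next(x for x in u_side if x in adj)
        rep_v = next(x for x in v_side if x in adj)
        comp_u = _component_nodes(adj, rep_u)
        comp_v = _component_nodes(adj, rep_v)
        att_u = _attachment_points(adj, comp_u, labels, nxt_id)
        att_v = _attachment_points(adj, comp_v, labels, nxt_id + 1)
        for mk_a in att_u:
            for mk_b in att_v:
                new_adj = {x: set(ns) for x, ns in adj.items()}
                a = mk_a(new_adj)
                b = mk_b(new_adj)
                new_adj.setdefault(a, set()).add(b)
                new_adj.setdefault(b, set()).add(a)
                t = Tree(new_adj, labels)
                if t not in seen:
                    seen.add(t)
                    yield t


def _component_nodes(adj: dict[int, set[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for w in adj.get(x, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _attachment_points(adj, comp: set[int], labels, new_node: int):
    """Closures that, applied to a working adjacency, return the node to join."""
    edges = [
        (a, b) for a in comp for b in adj.get(a, ()) if a < b and b in comp
    ]
    if not edges:
        (sole,) = comp
        return [lambda wa, s=sole: s]

    def subdivide(wa, a, b):
        wa[a].discard(b)
        wa[b].discard(a)
        wa[a].add(new_node)
        wa[b].add(new_node)
        wa[new_node] = {a, b}
        return new_node

    return [
        (lambda wa, a=a, b=b: subdivide(wa, a, b)) for a, b in edges
    ]


def nni_neighbors(tree: Tree) -> Iterator[Tree]:
    """Nearest-neighbor interchanges: two swaps per internal edge."""
    if not tree.is_binary or tree.n_leaves < 4:
        raise ValueError("NNI requires a binary tree with >= 4 leaves")
    labels = tree._labels
    seen: set[Tree] = {tree}
    for u, v in list(tree.edges()):
        if u in labels or v in labels:
            continue
        around_u = [x for x in tree._adj[u] if x != v]
        around_v = [x for x in tree._adj[v] if x != u]
        a, b = around_u
        c, d = around_v
        for x, y in ((a, c), (a, d)):
            adj = {n: set(ns) for n, ns in tree._adj.items()}
            adj[u].discard(x), adj[x].discard(u)
            adj[v].discard(y), adj[y].discard(v)
            adj[u].add(y), adj[y].add(u)
            adj[v].add(x), adj[x].add(v)
            t = Tree(adj, labels)
            if t not in seen:
                seen.add(t)
                yield t


# ---------------------------------------------------------------------------
# Consensus and split-based construction
# ---------------------------------------------------------------------------

def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """The tree whose splits are exactly those shared by every input tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("strict consensus of an empty tree set")
    leafset = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leafset:
            raise ValueError("trees must share one leaf set")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common = common & t.bipartitions()
    return tree_from_bipartitions(leafset, common)


def tree_from_bipartitions(
    leaves: frozenset[str], splits: Iterable[frozenset[str]]
) -> Tree:
    """Build the (possibly unresolved) tree realizing a compatible split set.

    Splits must be given in canonical orientation (block excluding the
    smallest label).  The construction roots at the smallest label and nests
    the blocks as a laminar family of clusters.
    """
    ref = min(leaves)
    clusters = {frozenset(leaves - {ref})}
    for s in splits:
        clusters.add(frozenset(s))
    singles = [frozenset({l}) for l in leaves if l != ref]
    family = sorted(clusters | set(singles), key=len, reverse=True)
    for s in family:
        for t in family:
            if s & t and not (s <= t or t <= s):
                raise ValueError("incompatible splits")
    node_of: dict[frozenset[str], int] = {}
    labels: dict[int, str] = {}
    edges: list[tuple[int, int]] = []
    nxt = 0
    for c in family:
        node_of[c] = nxt
        if len(c) == 1:
            (lab,) = c
            labels[nxt] = lab
        nxt += 1
    # parent = smallest strictly-containing cluster
    for c in family:
        best = None
        for p in family:
            if c < p and (best is None or len(p) < len(best)):
                best = p
        if best is not None:
            edges.append((node_of[c], node_of[best]))
    root_leaf = nxt
    labels[root_leaf] = ref
    edges.append((root_leaf, node_of[frozenset(leaves - {ref})]))
    return Tree.from_edges(edges, labels)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def tree_to_newick(
    tree: Tree,
    outgroup: str | None = None,
    support: Mapping[frozenset[str], float] | None = None,
) -> str:
    """Serialize to Newick, rooted basally on ``outgroup`` (or the smallest
    label).  ``support`` annotates internal nodes, keyed by clade leaf set."""
    root_label = outgroup if outgroup is not None else min(tree.leaves)
    rv = tree.rooted_at(root_label)

    def render(v: int) -> str:
        ch = rv.children[v]
        if not ch:
            return rv.label[v]
        inner = ",".join(render(c) for c in ch)
        ann = ""
        if support is not None:
            val = support.get(rv.clade_leaves(v))
            if val is not None:
                ann = format(val, "g")
        return f"({inner}){ann}"

    (top,) = rv.children[rv.root]
    return f"({rv.label[rv.root]},{render(top)});"


def tree_from_newick(text: str) -> tuple[Tree, dict[frozenset[str], float]]:
    """Parse a Newick string (through dendropy).

    Returns the unrooted :class:`Tree` and a mapping of clade leaf sets to
    numeric node annotations (bootstrap supports), empty when absent.
    Degree-2 nodes introduced by rooted input are suppressed.
    """
    import dendropy

    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    ids: dict = {}
    labels: dict[int, str] = {}
    adj: dict[int, set[int]] = {}
    support: dict[frozenset[str], float] = {}

    def nid(nd) -> int:
        if nd not in ids:
            ids[nd] = len(ids)
            adj[ids[nd]] = set()
        return ids[nd]

    for nd in dt.preorder_node_iter():
        v = nid(nd)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise ValueError("unlabelled leaf in Newick input")
            labels[v] = nd.taxon.label.replace(" ", "_")
        for c in nd.child_nodes():
            w = nid(c)
            adj[v].add(w)
            adj[w].add(v)
    for nd in dt.preorder_node_iter():
        if not nd.is_leaf() and nd.label is not None:
            try:
                val = float(nd.label)
            except ValueError:
                continue
            clade = frozenset(
                lf.taxon.label.replace(" ", "_") for lf in nd.leaf_iter()
            )
            support[clade] = val
    _suppress_degree_two(adj, labels)
    return Tree(adj, labels), support
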