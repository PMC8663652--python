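"""Parsimony lengths and homoplasy indices.

Three per-character optimization modes are supported:

``unordered``
    Fitch optimization: any state may change to any other at unit cost.
``ordered``
    Wagner (additive) optimization: states form a linear scale and a change
    of k units costs k steps, computed by the Farris interval method.
``irreversible``
    Gains only (Camin-Sokal style): transitions are permitted from lower to
    higher states only, with the ancestral state taken at the root of the
    evaluation (an outgroup-rooted view); columns that cannot be realized
    under that constraint score :data:`INFEASIBLE`.

Missing entries contribute the full state alphabet (unordered) or the full
state interval (ordered) at no cost.

The ensemble consistency index is Ci = sum(m)/sum(s) and the retention index
Ri = (sum(g)-sum(s))/(sum(g)-sum(m)), where per character m is the minimum
conceivable number of steps on any tree, s the observed steps, and g the
maximum conceivable steps (the star-tree length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, CharacterMatrix, CharacterTypeSpec
from .tree import Tree

__all__ = [
    "INFEASIBLE",
    "CharacterScore",
    "character_length",
    "tree_length",
    "min_steps",
    "max_steps",
    "homoplasy_indices",
    "round_half_up",
]

#: Sentinel length for an irreversible column with no admissible assignment.
INFEASIBLE = math.inf

_FULL_SET = (1 << 10) - 1
_STATE_LO, _STATE_HI = 0, 9


@dataclass(frozen=True)
class CharacterScore:
    """Step counts and fit indices for one character on one tree."""

    index: int
    mode: str
    steps: float  # s, observed
    min_steps: int  # m
    max_steps: int  # g

    @property
    def ci(self) -> float:
        return 1.0 if self.steps == 0 else self.min_steps / self.steps

    @property
    def ri(self) -> float:
        if self.max_steps == self.min_steps:
            return 1.0
        return (self.max_steps - self.steps) / (self.max_steps - self.min_steps)


def _column_states(tree: Tree, column) -> dict[str, int | None]:
    if isinstance(column, dict):
        col = column
    else:
        col = dict(zip(sorted(tree.leaves), column))
    missing = tree.leaves - set(col)
    if missing:
        raise ValueError(f"column lacks states for {sorted(missing)}")
    return col


def character_length(
    tree: Tree, column, mode: str = "unordered", root: str | None = None
) -> float:
    """Minimum number of steps for one character on ``tree``.

    ``column`` maps taxon label to a state in 0..9 or ``None`` for missing.
    ``root`` names the leaf used as evaluation root; for unordered and
    ordered characters the result is rooting-invariant, for irreversible
    characters the root leaf supplies the ancestral condition.
    """
    col = _column_states(tree, column)
    root_label = root if root is not None else min(tree.leaves)
    rv = tree.rooted_at(root_label)
    if mode == "unordered":
        return float(_fitch_length(rv, col))
    if mode == "ordered":
        return float(_wagner_length(rv, col))
    if mode == "irreversible":
        return _irreversible_length(rv, col)
    raise ValueError(f"unknown mode {mode!r}")


def _fitch_length(rv, col) -> int:
    sets: dict[int, int] = {}
    steps = 0
    for v in rv.postorder():
        ch = rv.children[v]
        if not ch:
            s = col[rv.label[v]]
            sets[v] = _FULL_SET if s is None else (1 << s)
        else:
            cur = None
            for c in ch:
                sc = sets[c]
                if cur is None:
                    cur = sc
                else:
                    inter = cur & sc
                    if inter:
                        cur = inter
                    else:
                        cur |= sc
                        steps += 1
            if v in rv.label:  # the root leaf also carries an observed state
                s = col[rv.label[v]]
                own = _FULL_SET if s is None else (1 << s)
                if cur & own:
                    cur &= own
                else:
                    steps += 1
                    cur = own
            sets[v] = cur
    return steps


def _wagner_length(rv, col) -> int:
    iv: dict[int, tuple[int, int]] = {}
    steps = 0
    for v in rv.postorder():
        ch = rv.children[v]
        if not ch:
            s = col[rv.label[v]]
            iv[v] = (_STATE_LO, _STATE_HI) if s is None else (s, s)
        else:
            cur = None
            for c in ch:
                lo2, hi2 = iv[c]
                if cur is None:
                    cur = (lo2, hi2)
                else:
                    lo, hi = max(cur[0], lo2), min(cur[1], hi2)
                    if lo <= hi:
                        cur = (lo, hi)
                    else:
                        steps += lo - hi
                        cur = (hi, lo)
            if v in rv.label:
                s = col[rv.label[v]]
                own = (_STATE_LO, _STATE_HI) if s is None else (s, s)
                lo, hi = max(cur[0], own[0]), min(cur[1], own[1])
                if lo <= hi:
                    cur = (lo, hi)
                else:
                    steps += lo - hi
                    cur = (hi, lo)
            iv[v] = cur
    return steps


def _irreversible_length(rv, col) -> float:
    """DP over states with transitions allowed only from lower to higher.

    The root leaf's observed state (0 when missing) is the fixed ancestral
    state; a leaf observed below it is unreachable, giving INFEASIBLE.
    """
    obs = [s for s in col.values() if s is not None]
    alpha = list(range(0, (max(obs) if obs else 0) + 1))
    INF = math.inf
    cost: dict[int, dict[int, float]] = {}
    for v in rv.postorder():
        ch = rv.children[v]
        if not ch:
            s = col[rv.label[v]]
            cost[v] = {a: (0.0 if s is None or a == s else INF) for a in alpha}
        else:
            acc = {}
            for a in alpha:
                tot = 0.0
                for c in ch:
                    tot += min(
                        cost[c][t] + (1 if t != a else 0)
                        for t in alpha
                        if t >= a
                    )
                acc[a] = tot
            if v in rv.label:
                s = col[rv.label[v]]
                for a in alpha:
                    if s is not None and a != s:
                        acc[a] = INF
            cost[v] = acc
    root_state = col[rv.label[rv.root]]
    if root_state is None:
        root_state = 0
    best = cost[rv.root].get(root_state, INF)
    return INFEASIBLE if math.isinf(best) else best


def tree_length(
    tree: Tree,
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    root: str | None = None,
) -> tuple[float, list[float]]:
    """Weighted total parsimony length and per-character step counts."""
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    per_char: list[float] = []
    total = 0.0
    for j in range(matrix.n_chars):
        if not spec.active[j]:
            per_char.append(0.0)
            continue
        s = character_length(tree, matrix.column(j), spec.modes[j], root=root)
        per_char.append(s)
        total += spec.weights[j] * s
    return total, per_char


def min_steps(column, mode: str = "unordered") -> int:
    """Minimum conceivable steps for a column on any binary tree."""
    obs = _observed(column)
    if not obs:
        raise ValueError("column has no non-missing entries")
    if mode == "ordered":
        return max(obs) - min(obs)
    return len(set(obs)) - 1


def max_steps(column, mode: str = "unordered") -> int:
    """Maximum conceivable steps: the length on the star (fully unresolved)
    tree, i.e. with all changes independent."""
    obs = _observed(column)
    if not obs:
        raise ValueError("column has no non-missing entries")
    if mode == "ordered":
        return min(sum(abs(x - c) for x in obs) for c in range(min(obs), max(obs) + 1))
    counts: dict[int, int] = {}
    for x in obs:
        counts[x] = counts.get(x, 0) + 1
    return len(obs) - max(counts.values())


def _observed(column) -> list[int]:
    vals = column.values() if isinstance(column, dict) else column
    return [int(v) for v in vals if v is not None and v != MISSING]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.765 -> 0.77), for display."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def homoplasy_indices(
    tree: Tree,
    matrix: CharacterMatrix,
    char_spec: CharacterTypeSpec | None = None,
    root: str | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Ensemble Ci and Ri plus the per-character score table.

    All active characters, parsimony-informative or not, enter the sums
    (uninformative characters have m == g and do not move Ri).  Weighted by
    the spec's character weights.
    """
    spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
    spec.validate_against(matrix)
    rows = []
    for j in range(matrix.n_chars):
        if not spec.active[j]:
            continue
        col = matrix.column(j)
        mode = spec.modes[j]
        smode = "ordered" if mode == "ordered" else "unordered"
        s = character_length(tree, col, mode, root=root)
        rows.append(
            CharacterScore(
                index=j,
                mode=mode,
                steps=s,
                min_steps=min_steps(col, smode),
                max_steps=max_steps(col, smode),
            )
        )
    w = np.array([spec.weights[r.index] for r in rows], dtype=float)
    s_sum = float(np.dot(w, [r.steps for r in rows]))
    m_sum = float(np.dot(w, [r.min_steps for r in rows]))
    g_sum = float(np.dot(w, [r.max_steps for r in rows]))
    ci = 1.0 if s_sum == 0 else m_sum / s_sum
    ri = 1.0 if g_sum == m_sum else (g_sum - s_sum) / (g_sum - m_sum)
    table = pd.DataFrame(
        {
            "character": [r.index for r in rows],
            "mode": [r.mode for r in rows],
            "steps": [r.steps for r in rows],
            "min_steps": [r.min_steps for r in rows],
            "max_steps": [r.max_steps for r in rows],
            "ci": [r.ci for r in rows],
            "ri": [r.ri for r in rows],
        }
    ).set_index("character")
    return ci, ri, table
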