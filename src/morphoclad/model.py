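"""Model/Results interface over the parsimony machinery.

:class:`ParsimonyAnalysis` is built from a character matrix (plus optional
per-character settings and an outgroup); :meth:`ParsimonyAnalysis.fit` runs
a tree search and returns a :class:`ParsimonyResults` carrying the MPT set,
tree length, homoplasy indices, consensus, and methods for bootstrap
support, character mapping and a text summary.
"""

from __future__ import annotations

import pandas as pd

from .bootstrap import CladeSupportTable, bootstrap_support
from .mapping import ChangeRecord, shared_changes_across_mpts, unambiguous_changes
from .matrix import CharacterMatrix, CharacterTypeSpec
from .parsimony import homoplasy_indices, round_half_up
from .search import (
    SearchResult,
    branch_and_bound_search,
    exhaustive_search,
    ratchet_search,
)
from .tree import Tree, strict_consensus, tree_to_newick

__all__ = ["ParsimonyAnalysis", "ParsimonyResults"]


class ParsimonyAnalysis:
    """Maximum-parsimony analysis of a discrete character matrix.

    Parameters
    ----------
    matrix : CharacterMatrix
    char_spec : CharacterTypeSpec, optional
        Defaults to all characters unordered, weight 1, active.
    outgroup : str, optional
        Taxon used to root result trees and polarize character changes;
        defaults to the first taxon of the matrix.
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        char_spec: CharacterTypeSpec | None = None,
        outgroup: str | None = None,
    ) -> None:
        self.matrix = matrix
        self.char_spec = char_spec or CharacterTypeSpec.uniform(matrix.n_chars)
        self.char_spec.validate_against(matrix)
        self.outgroup = outgroup or matrix.taxon_names[0]
        if self.outgroup not in matrix.taxon_names:
            raise KeyError(f"outgroup {self.outgroup!r} not in matrix")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        char_spec: CharacterTypeSpec | None = None,
        outgroup: str | None = None,
    ) -> "ParsimonyAnalysis":
        """Build from a taxa x characters DataFrame (NaN/None = missing)."""
        rows = []
        for _, row in frame.iterrows():
            rows.append([-1 if pd.isna(v) else int(v) for v in row])
        matrix = CharacterMatrix([str(i) for i in frame.index], rows)
        return cls(matrix, char_spec, outgroup)

    def fit(self, method: str = "auto", **settings) -> "ParsimonyResults":
        """Search for all minimum-length topologies.

        ``method``: ``"exhaustive"``, ``"branch_and_bound"``, ``"ratchet"``,
        or ``"auto"`` (exhaustive when the taxon count permits, otherwise
        branch-and-bound).  Extra keyword settings are passed through to the
        search function.
        """
        if method == "auto":
            method = "exhaustive" if self.matrix.n_taxa <= 9 else "branch_and_bound"
        if method == "exhaustive":
            res = exhaustive_search(self.matrix, self.char_spec, **settings)
        elif method == "branch_and_bound":
            res = branch_and_bound_search(self.matrix, self.char_spec, **settings)
        elif method == "ratchet":
            res = ratchet_search(self.matrix, self.char_spec, **settings)
        else:
            raise ValueError(f"unknown search method {method!r}")
        return ParsimonyResults(self, res)


class ParsimonyResults:
    """Fitted parsimony analysis: MPTs, fit indices, support, and mapping."""

    def __init__(self, model: ParsimonyAnalysis, search: SearchResult) -> None:
        self.model = model
        self.search = search
        self.length = search.best_length
        self.mpts: tuple[Tree, ...] = search.mpts
        ci, ri, table = homoplasy_indices(
            self.mpts[0], model.matrix, model.char_spec, root=model.outgroup
        )
        self.ci = ci
        self.ri = ri
        self.character_scores = table

    @property
    def n_mpts(self) -> int:
        return len(self.mpts)

    @property
    def consensus(self) -> Tree:
        return strict_consensus(self.mpts)

    def bootstrap(
        self, replications: int = 500, seed: int = 0, **settings
    ) -> CladeSupportTable:
        return bootstrap_support(
            self.model.matrix,
            self.model.char_spec,
            outgroup=self.model.outgroup,
            replications=replications,
            seed=seed,
            **settings,
        )

    def changes(self, tree: Tree | int | str = 0) -> list[ChangeRecord]:
        """Unambiguous change records.

        ``tree`` is an MPT index, a Tree, or ``"shared"`` for the
        intersection across all MPTs.
        """
        if isinstance(tree, str):
            if tree != "shared":
                raise ValueError("tree must be an index, a Tree, or 'shared'")
            return shared_changes_across_mpts(
                self.mpts, self.model.matrix, self.model.char_spec,
                self.model.outgroup,
            )
        t = self.mpts[tree] if isinstance(tree, int) else tree
        return unambiguous_changes(
            t, self.model.matrix, self.model.char_spec, self.model.outgroup
        )

    def changes_frame(self, tree: Tree | int | str = 0) -> pd.DataFrame:
        recs = self.changes(tree)
        return pd.DataFrame(
            {
                "clade": [",".join(sorted(r.clade)) for r in recs],
                "character": [r.character for r in recs],
                "from": [r.from_state for r in recs],
                "to": [r.to_state for r in recs],
                "classification": [r.classification for r in recs],
                "scope": [r.scope for r in recs],
            }
        )

    def newick(self, tree: int = 0, support: CladeSupportTable | None = None) -> str:
        sup = support.frequencies if support is not None else None
        return tree_to_newick(self.mpts[tree], outgroup=self.model.outgroup, support=sup)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Maximum parsimony results",
            "=" * 58,
            f"Taxa:                {m.matrix.n_taxa}",
            f"Characters:          {m.matrix.n_chars} "
            f"({sum(m.char_spec.active)} active)",
            f"Outgroup:            {m.outgroup}",
            f"Search method:       {self.search.method} "
            f"({self.search.evaluations} trees evaluated)",
            f"Tree length:         {self.length:g} steps",
            f"Most parsimonious trees: {self.n_mpts}",
            f"Consistency index Ci: {round_half_up(self.ci):.2f}  "
            f"(full precision {self.ci:.6f})",
            f"Retention index  Ri: {round_half_up(self.ri):.2f}  "
            f"(full precision {self.ri:.6f})",
            "-" * 58,
        ]
        for i in range(self.n_mpts):
            lines.append(f"MPT {i + 1}: {self.newick(i)}")
        lines.append(
            "Strict consensus: "
            + tree_to_newick(self.consensus, outgroup=m.outgroup)
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ParsimonyResults length={self.length:g} mpts={self.n_mpts} "
            f"ci={self.ci:.3f} ri={self.ri:.3f}>"
        )
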