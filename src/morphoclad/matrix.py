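"""Discrete morphological character matrices and per-character optimization settings.

A character matrix is a rectangular taxa-by-characters table of small integer
states (0..9) with ``?`` marking unknown entries.  Three interchange dialects
are supported: a plain whitespace table (label followed by a digit string),
NEXUS (DATA/CHARACTERS block, handled through dendropy), and TNT/Hennig86
``xread``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for an unknown ("?") entry in the integer state grid.
MISSING: int = -1

MAX_STATE = 9

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "CharacterTypeSpec",
    "MatrixFormatError",
    "parse_matrix",
    "write_matrix",
]


class MatrixFormatError(ValueError):
    """Raised for structural, symbol, or validation errors in matrix input."""


class CharacterMatrix:
    """An immutable taxa x characters grid of discrete states.

    Parameters
    ----------
    taxon_names : sequence of str
        Unique, non-empty row labels.
    states : array-like of int, shape (n_taxa, n_chars)
        Entries in ``0..9`` or :data:`MISSING`.
    """

    def __init__(self, taxon_names: Sequence[str], states) -> None:
        names = tuple(str(t) for t in taxon_names)
        if any(not t for t in names):
            raise MatrixFormatError("empty taxon name")
        if len(set(names)) != len(names):
            dup = sorted({t for t in names if names.count(t) > 1})
            raise MatrixFormatError(f"duplicate taxon name(s): {', '.join(dup)}")
        rows = [list(r) for r in states]
        if len(rows) != len(names):
            raise MatrixFormatError(
                f"{len(names)} taxon names but {len(rows)} state rows"
            )
        if not rows or not rows[0]:
            raise MatrixFormatError("matrix must have at least one character")
        width = len(rows[0])
        for name, r in zip(names, rows):
            if len(r) != width:
                raise MatrixFormatError(
                    f"ragged row for taxon {name!r}: {len(r)} entries, expected {width}"
                )
        grid = np.asarray(rows, dtype=np.int8)
        bad = (grid != MISSING) & ((grid < 0) | (grid > MAX_STATE))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"state out of range 0..{MAX_STATE} at taxon {names[i]!r}, character {j}"
            )
        all_missing = (grid == MISSING).all(axis=0)
        if all_missing.any():
            j = int(np.flatnonzero(all_missing)[0])
            raise MatrixFormatError(f"character {j} has no non-missing entries")
        grid.setflags(write=False)
        self._names = names
        self._grid = grid

    @property
    def taxon_names(self) -> tuple[str, ...]:
        return self._names

    @property
    def states(self) -> np.ndarray:
        """Read-only (n_taxa, n_chars) int8 grid; MISSING == -1."""
        return self._grid

    @property
    def n_taxa(self) -> int:
        return self._grid.shape[0]

    @property
    def n_chars(self) -> int:
        return self._grid.shape[1]

    def column(self, j: int) -> dict[str, int | None]:
        """Character ``j`` as a mapping taxon -> state (None for missing)."""
        col = self._grid[:, j]
        return {
            t: (None if s == MISSING else int(s)) for t, s in zip(self._names, col)
        }

    def row(self, taxon: str) -> np.ndarray:
        return self._grid[self._names.index(taxon)]

    def subset_characters(self, indices: Iterable[int]) -> "CharacterMatrix":
        idx = list(indices)
        return CharacterMatrix(self._names, self._grid[:, idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self._names == other._names
            and np.array_equal(self._grid, other._grid)
        )

    def __hash__(self) -> int:
        return hash((self._names, self._grid.tobytes()))

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_chars} characters>"


@dataclass(frozen=True)
class CharacterTypeSpec:
    """Per-character optimization mode, weight, and activity flag.

    ``modes[j]`` is one of ``"unordered"`` (Fitch), ``"ordered"``
    (Wagner/additive), or ``"irreversible"`` (gains only, Camin-Sokal style).
    Weights are positive integers; inactive characters are excluded from
    lengths and indices.
    """

    modes: tuple[str, ...]
    weights: tuple[int, ...] = field(default=())
    active: tuple[bool, ...] = field(default=())

    VALID_MODES = ("unordered", "ordered", "irreversible")

    def __post_init__(self):
        n = len(self.modes)
        if not self.weights:
            object.__setattr__(self, "weights", (1,) * n)
        if not self.active:
            object.__setattr__(self, "active", (True,) * n)
        for m in self.modes:
            if m not in self.VALID_MODES:
                raise ValueError(f"unknown character mode {m!r}")
        if len(self.weights) != n or len(self.active) != n:
            raise ValueError("modes, weights and active flags must have equal length")
        if any(w < 1 for w in self.weights):
            raise ValueError("character weights must be >= 1")

    @classmethod
    def uniform(cls, n_chars: int, mode: str = "unordered") -> "CharacterTypeSpec":
        return cls(modes=(mode,) * n_chars)

    @property
    def n_chars(self) -> int:
        return len(self.modes)

    def validate_against(self, matrix: CharacterMatrix) -> None:
        if self.n_chars != matrix.n_chars:
            raise ValueError(
                f"spec covers {self.n_chars} characters, matrix has {matrix.n_chars}"
            )


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_DIALECTS = ("plain", "nexus", "tnt")


def parse_matrix(text: str, dialect: str = "plain") -> CharacterMatrix:
    """Parse a character matrix from ``text`` in the named dialect.

    Plain dialect: one taxon per line, a whitespace-separated label followed
    by its digit string (internal whitespace in the digit string is ignored,
    so column blocks may be pasted as printed).  An optional leading line of
    two integers declares ``ntax nchar`` and is checked.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    if dialect == "plain":
        return _parse_plain(text)
    if dialect == "tnt":
        return _parse_tnt(text)
    return _parse_nexus(text)


def write_matrix(matrix: CharacterMatrix, dialect: str = "plain") -> str:
    """Serialize ``matrix`` so that ``parse_matrix`` recovers it exactly."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    if dialect == "plain":
        return _write_plain(matrix)
    if dialect == "tnt":
        return _write_tnt(matrix)
    return _write_nexus(matrix)


def _row_to_symbols(row: np.ndarray) -> str:
    return "".join("?" if s == MISSING else str(int(s)) for s in row)


def _symbols_to_states(sym: str, taxon: str, line_no: int) -> list[int]:
    out = []
    for pos, ch in enumerate(sym):
        if ch == "?":
            out.append(MISSING)
        elif ch.isdigit():
            out.append(int(ch))
        else:
            raise MatrixFormatError(
                f"undeclared symbol {ch!r} for taxon {taxon!r} "
                f"(line {line_no}, character {pos})"
            )
    return out


def _parse_plain(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixFormatError("empty input")
    declared = None
    first = lines[0].split()
    if len(first) == 2 and all(tok.isdigit() for tok in first):
        declared = (int(first[0]), int(first[1]))
        lines = lines[1:]
    names, rows = [], []
    for i, ln in enumerate(lines, start=1):
        toks = ln.split()
        if len(toks) < 2:
            raise MatrixFormatError(f"line {i}: expected 'label states'")
        label = toks[0]
        names.append(label)
        rows.append(_symbols_to_states("".join(toks[1:]), label, i))
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        ref = len(rows[0])
        for name, r in zip(names, rows):
            if len(r) != ref:
                raise MatrixFormatError(
                    f"ragged row for taxon {name!r}: {len(r)} characters, "
                    f"first row has {ref}"
                )
    m = CharacterMatrix(names, rows)
    if declared is not None and (m.n_taxa, m.n_chars) != declared:
        raise MatrixFormatError(
            f"declared dimensions {declared} do not match parsed "
            f"({m.n_taxa}, {m.n_chars})"
        )
    return m


def _write_plain(matrix: CharacterMatrix) -> str:
    width = max(len(t) for t in matrix.taxon_names) + 2
    lines = [f"{matrix.n_taxa} {matrix.n_chars}"]
    for t, row in zip(matrix.taxon_names, matrix.states):
        lines.append(f"{t.ljust(width)}{_row_to_symbols(row)}")
    return "\n".join(lines) + "\n"


# -- NEXUS (through dendropy) ------------------------------------------------

def _parse_nexus(text: str) -> CharacterMatrix:
    import dendropy

    try:
        cm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise MatrixFormatError(f"NEXUS parse error: {exc}") from exc
    names, rows = [], []
    for taxon in cm.taxon_namespace:
        vec = cm[taxon]
        row = []
        for cell in vec:
            sym = cell.symbol
            if sym == "?":
                row.append(MISSING)
                continue
            if sym is None or not cell.is_single_state:
                raise MatrixFormatError(
                    f"polymorphic/ambiguous state for taxon {taxon.label!r} "
                    "is not supported by this analysis"
                )
            if sym.isdigit():
                row.append(int(sym))
            else:
                raise MatrixFormatError(
                    f"undeclared symbol {sym!r} for taxon {taxon.label!r}"
                )
        names.append(taxon.label)
        rows.append(row)
    return CharacterMatrix(names, rows)


def _write_nexus(matrix: CharacterMatrix) -> str:
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    buf.write('    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=?;\n')
    buf.write("    MATRIX\n")
    width = max(len(t) for t in matrix.taxon_names) + 2
    for t, row in zip(matrix.taxon_names, matrix.states):
        label = f"'{t}'" if re.search(r"\s", t) else t
        buf.write(f"        {label.ljust(width + 2)}{_row_to_symbols(row)}\n")
    buf.write("    ;\nEND;\n")
    return buf.getvalue()


# -- TNT / Hennig86 xread ----------------------------------------------------

def _parse_tnt(text: str) -> CharacterMatrix:
    # strip comments and locate the xread block
    body = re.sub(r"'[^']*'", " ", text)  # quoted title
    m = re.search(r"xread\b(.*?);", body, flags=re.S | re.I)
    if not m:
        raise MatrixFormatError("no xread block found")
    toks = m.group(1).split()
    if len(toks) < 2 or not toks[0].isdigit() or not toks[1].isdigit():
        raise MatrixFormatError("xread must declare 'nchar ntax'")
    nchar, ntax = int(toks[0]), int(toks[1])
    toks = toks[2:]
    names, rows = [], []
    i = 0
    while i < len(toks):
        label = toks[i]
        i += 1
        sym = ""
        while i < len(toks) and len(sym) < nchar:
            chunk = toks[i]
            if not all(c.isdigit() or c == "?" for c in chunk):
                break
            sym += chunk
            i += 1
        if "{" in sym or "[" in sym:
            raise MatrixFormatError("polymorphic states are not supported")
        names.append(label)
        rows.append(_symbols_to_states(sym, label, 0))
    m_out = CharacterMatrix(names, rows)
    if (m_out.n_taxa, m_out.n_chars) != (ntax, nchar):
        raise MatrixFormatError(
            f"xread declares ({ntax} taxa, {nchar} characters) but parsed "
            f"({m_out.n_taxa}, {m_out.n_chars})"
        )
    return m_out


def _write_tnt(matrix: CharacterMatrix) -> str:
    lines = ["xread", f"{matrix.n_chars} {matrix.n_taxa}"]
    width = max(len(t) for t in matrix.taxon_names) + 2
    for t, row in zip(matrix.taxon_names, matrix.states):
        safe = t.replace(" ", "_")
        lines.append(f"{safe.ljust(width)}{_row_to_symbols(row)}")
    lines.append(";")
    return "\n".join(lines) + "\n"
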