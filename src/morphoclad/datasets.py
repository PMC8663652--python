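"""Bundled study dataset.

The package ships the published morphological matrix for the laophontodid
harpacticoid genus *Bicorniphontodes* (six ingroup species) with
*Laophontodes typicus* as outgroup: 7 taxa by 41 characters, states 0-2,
``?`` unknown.  Characters are coded with 0 as the presumed plesiomorphic
state and 1-2 as successively derived states under the "oligomerization"
premise (progressive fusion/loss of appendage elements), so every character
is optimized as ordered (additive) by default.  The two ``?`` entries sit in
the *B. bicornis* row (characters 25-26, maxillule characters unknown from
the original description).
"""

from __future__ import annotations

from .matrix import CharacterMatrix, CharacterTypeSpec, parse_matrix

__all__ = ["load_bicorniphontodes", "BICORNIPHONTODES_OUTGROUP"]

BICORNIPHONTODES_OUTGROUP = "Laophontodes_typicus"

# 0-based character indices 0..40 run left to right.
_TABLE = """\
7 41
Laophontodes_typicus          1000000001 0000000010 1111110010 1101100110 2
Bicorniphontodes_bicornis     1111100100 0000000100 10010??000 1111000011 2
Bicorniphontodes_clarae       1111110201 0100000100 0110011111 1011100011 2
Bicorniphontodes_horstgeorgei 0011101111 0010100110 0000111100 1111100012 2
Bicorniphontodes_lacuna       0011112201 0111100110 0000000100 0110110000 0
Bicorniphontodes_comptus      0111101201 0110110111 0000000100 0110100000 1
Bicorniphontodes_huysi        0011101001 1110101100 0000000100 0110101000 1
"""


def load_bicorniphontodes() -> tuple[CharacterMatrix, CharacterTypeSpec, str]:
    """Return the bundled study data.

    Returns
    -------
    (matrix, char_spec, outgroup)
        The 7 x 41 matrix, a spec marking every character ordered with unit
        weight, and the outgroup taxon label used for rooting.
    """
    matrix = parse_matrix(_TABLE, dialect="plain")
    spec = CharacterTypeSpec.uniform(matrix.n_chars, mode="ordered")
    return matrix, spec, BICORNIPHONTODES_OUTGROUP
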