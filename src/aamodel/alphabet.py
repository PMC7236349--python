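"""The 20-letter amino-acid alphabet in canonical (PAML) order.

All matrices and frequency vectors in this package are indexed in this
order; model files in other orders must be re-indexed on load.
"""

from __future__ import annotations

AMINO_ACIDS: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)

THREE_LETTER: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

N_STATES = 20

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
AA_INDEX.update({t: i for i, t in enumerate(THREE_LETTER)})
AA_INDEX.update({t.upper(): i for i, t in enumerate(THREE_LETTER)})

#: ambiguity codes resolved to candidate residue sets
AMBIGUITY: dict[str, tuple[str, ...]] = {
    "B": ("N", "D"),
    "Z": ("Q", "E"),
    "J": ("I", "L"),
}

#: states carrying no information (partial likelihood 1 for every residue)
UNKNOWN_STATES: frozenset[str] = frozenset({"-", "X", "?", "*", "."})


def index_of(code: str) -> int:
    """Index of a residue given its one- or three-letter code."""
    try:
        return AA_INDEX[code if len(code) == 1 else code.capitalize()]
    except KeyError:
        raise KeyError(f"unknown amino-acid code: {code!r}") from None
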