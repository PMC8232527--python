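"""Sequence alphabets and validation.

Sequences are carried as plain Python strings; the functions here are the
single entry point that guarantees the alphabet invariants the rest of the
package relies on (RNA over A/C/G/U with T already folded into U, proteins
over the 20 standard amino acids, no ambiguity codes).
"""

from __future__ import annotations

RNA_ALPHABET = "ACGU"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_RNA_SET = frozenset(RNA_ALPHABET)
_PROTEIN_SET = frozenset(PROTEIN_ALPHABET)


class AlphabetError(ValueError):
    """A residue outside the declared alphabet (position is 0-based)."""

    def __init__(self, residue: str, position: int, alphabet: str):
        self.residue = residue
        self.position = position
        self.alphabet = alphabet
        super().__init__(
            f"invalid {alphabet} residue {residue!r} at position {position}"
        )


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and fold thymine into uracil.

    Accepts DNA or RNA input (case-insensitive); every ``T`` becomes ``U``
    so downstream encoders see a uniform 4-letter RNA alphabet. Length is
    preserved. Raises :class:`AlphabetError` on the first character outside
    ``{A, C, G, T, U}`` and :class:`ValueError` on empty input.
    """
    if not seq:
        raise ValueError("empty nucleotide sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in "ACGTU":
            raise AlphabetError(ch, i, "nucleotide")
    return up.replace("T", "U")


def check_rna(seq: str) -> str:
    """Validate a normalized RNA sequence (no T allowed) and return it."""
    if not seq:
        raise ValueError("empty RNA sequence")
    for i, ch in enumerate(seq):
        if ch not in _RNA_SET:
            raise AlphabetError(ch, i, "RNA")
    return seq


def check_protein(seq: str) -> str:
    """Validate a protein sequence over the 20 standard amino acids.

    Ambiguity codes (B, J, O, U, X, Z) are rejected rather than imputed.
    """
    if not seq:
        raise ValueError("empty protein sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _PROTEIN_SET:
            raise AlphabetError(ch, i, "protein")
    return up
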