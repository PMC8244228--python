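"""Small sequence utilities: gap handling, IUPAC codes, strand transforms."""

from __future__ import annotations

GAP_CHARS = frozenset("-?")

# IUPAC nucleotide ambiguity codes -> base sets
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN-?",
    "TGCAAYRSWMKVHDBN-?",
)


def ungap(seq: str) -> str:
    """Strip gap ('-') and missing ('?') characters."""
    return "".join(c for c in seq if c not in GAP_CHARS)


def ungapped_length(seq: str) -> int:
    """Number of non-gap, non-missing characters. Ambiguity codes (incl. N)
    count as sequence."""
    return sum(1 for c in seq if c not in GAP_CHARS)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse(seq: str) -> str:
    return seq[::-1]


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


#: orientation tag -> transform, in tie-break priority order
ORIENTATIONS = (
    ("forward", lambda s: s),
    ("reverse-complement", reverse_complement),
    ("reverse", reverse),
    ("complement", complement),
)
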