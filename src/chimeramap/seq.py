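"""Sequence alphabet utilities.

All sequences are stored in the DNA alphabet: RNA input (U) is normalized
to T at ingest, and every matching/complementation operation below works
on DNA strings.  Wobble pairing (G:U) is evaluated on the DNA-encoded
bases (G:T).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def normalize(sequence: str) -> str:
    """Uppercase and convert U to T."""
    return sequence.strip().upper().replace("U", "T")


def revcomp(sequence: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def is_wc_pair(a: str, b: str) -> bool:
    """Watson-Crick pair between two DNA-encoded bases."""
    return (a, b) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


def is_wobble_pair(a: str, b: str) -> bool:
    """G:U wobble, written G:T in the DNA alphabet."""
    return (a, b) in (("G", "T"), ("T", "G"))


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or wobble."""
    return is_wc_pair(a, b) or is_wobble_pair(a, b)


def pair_score(a: str, b: str) -> int:
    """Duplex pair score: GC=3, AT(AU)=2, GT(GU wobble)=1, else 0."""
    if (a, b) in (("G", "C"), ("C", "G")):
        return 3
    if (a, b) in (("A", "T"), ("T", "A")):
        return 2
    if (a, b) in (("G", "T"), ("T", "G")):
        return 1
    return 0


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
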