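"""Small shared sequence helpers."""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, what: str = "sequence") -> None:
    """Raise ValueError unless seq is a non-empty upper-case A/C/G/T string."""
    if not seq:
        raise ValueError(f"{what} is empty")
    if not DNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"{what} contains non-ACGT symbols: {bad}")


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Map each k-word of seq to its (sorted) start positions."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def word_set(seq: str, k: int, both_strands: bool = True) -> set[str]:
    words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    if both_strands:
        rc = revcomp(seq)
        words.update(rc[i : i + k] for i in range(len(rc) - k + 1))
    return words


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up.

    Python's built-in round() uses banker's rounding, which disagrees with
    the arithmetic convention used throughout the copy-number tables here.
    """
    import math

    return math.floor(x + 0.5)
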