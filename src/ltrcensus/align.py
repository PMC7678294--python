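"""Pairwise global-alignment identity."""

from __future__ import annotations

import edlib


def aligned_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Defined as ``1 - d / max(|a|, |b|)`` where ``d`` is the Levenshtein
    (unit-cost global alignment) distance.  For substitution-only
    differences this equals matches over alignment columns; with indels the
    shorter sequence's missing columns count as mismatches.  Symmetric and
    deterministic (no dependence on which optimal alignment is traced).

    Raises ValueError on an empty sequence.
    """
    if not a or not b:
        raise ValueError("aligned_identity requires two non-empty sequences")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))
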