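"""Genome proportion and copy number of repeat families from raw reads.

High-copy repeats dominate unassembled shotgun data even when the
assembler has collapsed them into a single contig, so the read pool itself
is the census: the fraction of reads attributable to a family, multiplied
by genome size, gives the family's total bp; divided by element length it
gives the copy number.

A read is attributed to an element by word containment: the fraction of
the read's k-words found in the element's word set (either strand).  Each
read goes to at most one element — the best containment at or above the
floor, ties broken by lexicographic element id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ltrcensus._seq import round_half_up, word_set
from ltrcensus.synthgenome import ReadSet


@dataclass(frozen=True)
class CensusParams:
    k: int = 13
    min_containment: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_containment <= 1:
            raise ValueError("min_containment must lie in (0, 1]")
        if self.k < 8:
            raise ValueError("k must be >= 8")


@dataclass
class CensusRow:
    """Per-element read counts and fractions across read datasets."""

    element_id: str
    element_len: int
    counts: dict[str, int] = field(default_factory=dict)  # platform -> reads
    totals: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)  # raw, unrounded

    def fraction_rounded(self, platform: str, ndigits: int = 3) -> float:
        return round(self.fractions[platform], ndigits)


def assign_reads(
    reads: ReadSet,
    consensi: list[tuple[str, str]],
    params: CensusParams | None = None,
) -> dict[str, int]:
    """Count reads per element for one read set.

    Returns {element_id: read_count}; reads whose best containment is below
    the floor stay unassigned and are not returned.
    """
    params = params or CensusParams()
    if not consensi:
        raise ValueError("consensi must be non-empty")
    k = params.k
    for eid, seq in consensi:
        if len(seq) < k:
            raise ValueError(f"element {eid!r} shorter than k={k}")
    elem_words = {eid: word_set(seq, k, both_strands=True) for eid, seq in consensi}
    order = sorted(elem_words)  # lexicographic tie-break

    counts = {eid: 0 for eid, _ in consensi}
    for _, seq in reads.reads:
        n = len(seq) - k + 1
        if n <= 0:
            continue
        read_words = [seq[i : i + k] for i in range(n)]
        best_id, best_score = None, 0.0
        for eid in order:
            words = elem_words[eid]
            score = sum(1 for w in read_words if w in words) / n
            if score > best_score:
                best_id, best_score = eid, score
        if best_id is not None and best_score >= params.min_containment:
            counts[best_id] += 1
    return counts


def census_fractions(
    counts: dict[str, dict[str, int]],
    totals: dict[str, int],
    element_lens: dict[str, int],
) -> list[CensusRow]:
    """Build census rows from per-platform counts and dataset totals.

    ``counts`` maps platform -> {element_id: read_count}.  Fractions are
    kept raw; display rounding to three decimals is applied at I/O time.
    """
    for platform, total in totals.items():
        if total <= 0:
            raise ValueError(f"total for {platform!r} must be positive")
    element_ids = sorted({eid for per in counts.values() for eid in per})
    rows = []
    for eid in element_ids:
        row = CensusRow(element_id=eid, element_len=element_lens.get(eid, 0))
        for platform, total in totals.items():
            c = counts.get(platform, {}).get(eid, 0)
            if not 0 <= c <= total:
                raise ValueError("read_count must lie in [0, total]")
            row.counts[platform] = c
            row.totals[platform] = total
            row.fractions[platform] = c / total
        rows.append(row)
    return rows


def copies_from_fraction(
    fraction: float, genome_bp: float, element_len: int
) -> tuple[float, int]:
    """Convert a read fraction into (target_bp, copies per genome).

    target_bp = fraction x genome size; copies = target_bp / element
    length, rounded half-up to the nearest integer.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if genome_bp <= 0 or element_len <= 0:
        raise ValueError("genome_bp and element_len must be positive")
    target_bp = fraction * genome_bp
    return target_bp, round_half_up(target_bp / element_len)


def census_to_tsv(rows: list[CensusRow], platforms: list[str] | None = None) -> str:
    """Census table: per-platform counts then per-platform fractions (3 dp),
    with a totals row."""
    if not rows:
        return "element\tsize\n"
    platforms = platforms or sorted(rows[0].totals)
    header = (
        ["element", "size"]
        + platforms
        + [f"%{p}" for p in platforms]
    )
    lines = ["\t".join(header)]
    for row in rows:
        lines.append(
            "\t".join(
                [row.element_id, str(row.element_len)]
                + [str(row.counts[p]) for p in platforms]
                + [f"{row.fraction_rounded(p):.3f}" for p in platforms]
            )
        )
    lines.append(
        "\t".join(["Total", ""] + [str(rows[0].totals[p]) for p in platforms] + [""] * len(platforms))
    )
    return "\n".join(lines) + "\n"
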