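"""Structural detection of full-length LTR retrotransposon candidates.

A full-length element is recognised purely from its architecture: two
near-identical long terminal repeats (direct repeats) separated by an
internal region, the whole spanning a few to a few tens of kilobases.  The
detector is a seed–band–extend scheme:

1. index every k-word of the contig;
2. collect word match pairs (i, j), i < j, whose implied element span
   lies inside the configured length window;
3. group pairs into diagonal bands (same separation up to a small drift)
   and chain collinear matches within a band;
4. extend each band outward into two terminal blocks with an X-drop walk;
5. score the block pair by global-alignment identity and keep candidates
   that satisfy the length and identity bounds, optionally annotating a
   flanking 4-6 bp exact target-site duplication;
6. resolve overlaps by keeping the higher-identity candidate (ties: the
   longer, then the leftmost).

Because the two repeats of an element are direct repeats, the architecture
is strand-symmetric: a single forward scan finds the same intervals a
reverse-complement scan would, so candidates are reported once in forward
contig coordinates with strand '+'.
"""

from __future__ import annotations

from dataclasses import dataclass

from ltrcensus._seq import check_dna, kmer_positions
from ltrcensus.align import aligned_identity
from ltrcensus.synthgenome import Contig


@dataclass(frozen=True)
class DetectParams:
    """Detection bounds; defaults bracket typical plant LTR element geometry
    (repeats of a few hundred bp to ~3 kb, elements up to ~20 kb)."""

    k: int = 13
    min_ltr: int = 100
    max_ltr: int = 3000
    min_elem: int = 1500
    max_elem: int = 20_000
    min_identity: float = 0.80
    tsd_search: bool = True
    drift: int = 20  # diagonal tolerance when banding word matches

    def __post_init__(self) -> None:
        if not (0 < self.min_ltr <= self.max_ltr < self.max_elem):
            raise ValueError("require 0 < min_ltr <= max_ltr < max_elem")
        if not (0 < self.min_elem <= self.max_elem):
            raise ValueError("require 0 < min_elem <= max_elem")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.k < 8:
            raise ValueError("k must be >= 8")


@dataclass(frozen=True)
class LTRCandidate:
    """One detected element; coordinates 0-based half-open on the contig."""

    contig_id: str
    elem_start: int
    elem_end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    internal: tuple[int, int]
    ltr_identity: float
    tsd: str
    strand: str = "+"

    @property
    def total_len(self) -> int:
        return self.elem_end - self.elem_start


#: log-likelihood-ratio weight of a mismatch column relative to a match,
#: for ~90% within-repeat vs 25% background per-base match rates
_MISMATCH_WEIGHT = 1.6

#: largest gap (bp) between consecutive seed matches inside one repeat pair;
#: word matches within a repeat at <=10% pairwise divergence are far denser
_MAX_SEED_GAP = 200

#: minimum word matches supporting a candidate repeat pair
_MIN_SEED_PAIRS = 3


def _refine_boundary(
    seq: str,
    a: int,
    b: int,
    step: int,
    limit_a: int,
    limit_b: int,
    window: int = 200,
    inward: int = 60,
) -> int:
    """Maximum-likelihood placement of one repeat boundary.

    Scans from `inward` columns inside the current edge (seq[a] paired with
    seq[b]) to `window` columns outside it, scoring match +1 / mismatch
    -1.6 (the log-likelihood-ratio weighting for ~90% within-repeat vs 25%
    background per-base match rates), and returns the signed offset of the
    global score maximum — the most likely point where repeat homology
    gives way to background.  Positive offsets extend the block, negative
    ones retract an edge that a chance word match had inflated.  A gain of
    more than +2 over the current edge is demanded before the edge moves,
    so one or two chance-matching background bases never drag a perfect
    boundary outward.
    """
    score = 0.0
    best, best_t = None, 0
    at_zero = 0.0
    for t in range(-inward + 1, window + 1):
        pa, pb = a + t * step, b + t * step
        if pa < 0 or pb < 0 or pa >= len(seq) or pb >= len(seq):
            break
        if t > 0:
            if step < 0 and (pa < limit_a or pb < limit_b):
                break
            if step > 0 and (pa >= limit_a or pb >= limit_b):
                break
        score += 1.0 if seq[pa] == seq[pb] else -_MISMATCH_WEIGHT
        if best is None or score > best:
            best, best_t = score, t
        if t == 0:
            at_zero = score
    if best is None or best <= at_zero + 2.0:
        return 0
    return best_t


#: per-base log-likelihood bonus of an exactly duplicated flank base
#: (a 1-in-4 chance under background): log 4
_TSD_BASE_BONUS = 1.386

#: additional prior bonus when any 4-6 bp duplication is present at all:
#: integration essentially always leaves a target-site duplication, so
#: boundary placements that exhibit one are strongly favoured over
#: placements that do not
_TSD_PRESENT_BONUS = 5.0

#: flanking duplication lengths accepted as a target-site duplication
_TSD_LENGTHS = (6, 5, 4)


def _snap_tsd(
    seq: str, i0: int, i1: int, j0: int, j1: int, wiggle: int = 15
) -> tuple[int, int, int, int, str]:
    """Joint MAP placement of both element boundaries with a TSD bonus.

    Element boundaries live at the outer edges of the two repeat blocks
    [i0,i1) and [j0,j1).  For every pair of boundary offsets (ds, de) up to
    `wiggle` bp the posterior score is the sum of the two change-point
    log-likelihood profiles plus log(4) per base of an exact 4-6 bp
    flanking duplication at those offsets — an integration-generated
    target-site duplication is a 4^-t coincidence under background, so its
    presence outweighs the small chance excursions that otherwise drag a
    maximum-likelihood boundary a few bases into the host.  The paired
    inner edges (j0, i1) shift with their outer partners.  Ties prefer the
    smallest offsets.  Returns (i0, i1, j0, j1, tsd).
    """
    n = len(seq)
    w = wiggle

    # change-point profiles: S_left[ds] = sum of column LLRs from offset ds
    # inward; S_right[de] = the mirror for the right boundary
    def llr(a: int, b: int) -> float:
        if a < 0 or b < 0 or a >= n or b >= n:
            return -_MISMATCH_WEIGHT
        return 1.0 if seq[a] == seq[b] else -_MISMATCH_WEIGHT

    left_cols = [llr(i0 + u, j0 + u) for u in range(-w, w + 1)]
    s_left = {}
    acc = 0.0
    for idx in range(len(left_cols) - 1, -1, -1):
        acc += left_cols[idx]
        s_left[idx - w] = acc
    right_cols = [llr(i1 + u, j1 + u) for u in range(-w, w + 1)]
    s_right = {-w: 0.0}
    acc = 0.0
    for idx in range(len(right_cols)):
        acc += right_cols[idx]
        s_right[idx - w + 1] = acc  # boundary after column idx

    def tsd_at(s: int, e: int) -> str:
        for t in _TSD_LENGTHS:
            if s >= t and e + t <= n and seq[s - t : s] == seq[e : e + t]:
                return seq[s - t : s]
        return ""

    best_key = None
    best = (0, 0, "")
    for ds in range(-w, w + 1):
        for de in range(-w, w + 1):
            s, e = i0 + ds, j1 + de
            if e - s <= 0:
                continue
            tsd = tsd_at(s, e)
            score = s_left[ds] + s_right[de] + _TSD_BASE_BONUS * len(tsd)
            if tsd:
                score += _TSD_PRESENT_BONUS
            key = (-score, abs(ds) + abs(de), abs(ds), ds, de)
            if best_key is None or key < best_key:
                best_key, best = key, (ds, de, tsd)
    ds, de, tsd = best
    new_i0, new_j1 = i0 + ds, j1 + de
    new_j0 = min(j0 + ds, new_j1)
    new_i1 = max(min(i1 + de, new_j0), new_i0)
    return new_i0, new_i1, new_j0, new_j1, tsd


def find_ltr_elements(contig: Contig, params: DetectParams | None = None) -> list[LTRCandidate]:
    """Detect full-length LTR element candidates in one contig.

    Deterministic: the same contig and parameters always yield the same
    candidate list.  A contig shorter than ``min_elem`` yields an empty
    list.
    """
    params = params or DetectParams()
    seq = contig.seq
    check_dna(seq, f"contig {contig.id!r}")
    if len(seq) < params.min_elem:
        return []

    k = params.k
    # separation between homologous LTR positions is elem_len - ltr_len,
    # so it is at least min_elem - max_ltr and also at least min_ltr
    # (the two repeats cannot overlap)
    sep_lo = max(params.min_elem - params.max_ltr - k, params.min_ltr)
    sep_hi = params.max_elem - k

    # word match pairs as (separation, left position)
    pairs: list[tuple[int, int]] = []
    for positions in kmer_positions(seq, k).values():
        if len(positions) < 2:
            continue
        for ai, i in enumerate(positions):
            for j in positions[ai + 1 :]:
                sep = j - i
                if sep < sep_lo:
                    continue
                if sep > sep_hi:
                    break
                pairs.append((sep, i))
    if not pairs:
        return []

    pairs.sort()
    # band by separation, then split bands whose matches are not collinear
    bands: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = [pairs[0]]
    for p in pairs[1:]:
        if p[0] - cur[-1][0] <= params.drift:
            cur.append(p)
        else:
            bands.append(cur)
            cur = [p]
    bands.append(cur)

    candidates: list[LTRCandidate] = []
    for band in bands:
        band.sort(key=lambda p: p[1])
        # split a band into seed groups: within one repeat pair the word
        # matches are dense, so a gap above _MAX_SEED_GAP separates distinct
        # repeat pairs (or strands a chance match on the same diagonal)
        groups: list[list[tuple[int, int]]] = [[band[0]]]
        for p in band[1:]:
            if p[1] - groups[-1][-1][1] > _MAX_SEED_GAP:
                groups.append([p])
            else:
                groups[-1].append(p)
        for grp in groups:
            if len(grp) < _MIN_SEED_PAIRS:
                continue
            i0 = min(i for _, i in grp)
            i1 = max(i for _, i in grp) + k
            j0 = min(i + s for s, i in grp)
            j1 = max(i + s for s, i in grp) + k
            # refine both edges; the left block must not run into the right
            inward = min(max(i1 - i0 - k, 1), 300)
            ext_l = _refine_boundary(seq, i0, j0, -1, 0, i1, inward=inward)
            i0 -= ext_l
            j0 -= ext_l
            ext_r = _refine_boundary(seq, i1 - 1, j1 - 1, +1, j0, len(seq), inward=inward)
            i1 += ext_r
            j1 += ext_r
            if i1 > j0:  # degenerate: blocks collided
                continue
            tsd = ""
            if params.tsd_search:
                i0, i1, j0, j1, tsd = _snap_tsd(seq, i0, i1, j0, j1)
            ltr_len = i1 - i0
            total = j1 - i0
            if not (params.min_ltr <= ltr_len <= params.max_ltr):
                continue
            if not (params.min_ltr <= j1 - j0 <= params.max_ltr):
                continue
            if not (params.min_elem <= total <= params.max_elem):
                continue
            ident = aligned_identity(seq[i0:i1], seq[j0:j1])
            if ident < params.min_identity:
                continue
            candidates.append(
                LTRCandidate(
                    contig_id=contig.id,
                    elem_start=i0,
                    elem_end=j1,
                    ltr5=(i0, i1),
                    ltr3=(j0, j1),
                    internal=(i1, j0),
                    ltr_identity=ident,
                    tsd=tsd,
                )
            )

    # overlap resolution: higher identity wins; ties -> longer, then leftmost
    candidates.sort(key=lambda c: (-c.ltr_identity, -c.total_len, c.elem_start))
    kept: list[LTRCandidate] = []
    for c in candidates:
        if all(c.elem_end <= o.elem_start or c.elem_start >= o.elem_end for o in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.elem_start)
    return kept


# ---------------------------------------------------------------------------
# writers


def candidates_to_gff3(candidates: list[LTRCandidate]) -> str:
    """GFF3 text with LTR_retrotransposon parents and long_terminal_repeat
    children; coordinates converted to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for n, c in enumerate(candidates, 1):
        eid = f"ltr_elem{n}"
        attrs = f"ID={eid};ltr_identity={c.ltr_identity:.4f}"
        if c.tsd:
            attrs += f";tsd={c.tsd}"
        lines.append(
            "\t".join(
                [
                    c.contig_id,
                    "ltrcensus",
                    "LTR_retrotransposon",
                    str(c.elem_start + 1),
                    str(c.elem_end),
                    ".",
                    c.strand,
                    ".",
                    attrs,
                ]
            )
        )
        for tag, (s, e) in (("five_prime", c.ltr5), ("three_prime", c.ltr3)):
            lines.append(
                "\t".join(
                    [
                        c.contig_id,
                        "ltrcensus",
                        "long_terminal_repeat",
                        str(s + 1),
                        str(e),
                        ".",
                        c.strand,
                        ".",
                        f"ID={eid}_{tag};Parent={eid}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def candidates_to_tsv(candidates: list[LTRCandidate]) -> str:
    """Per-element table: total, LTR and internal (coding-region) lengths."""
    lines = ["element\tcontig\tstart\tend\ttotal_length\tltr_length\tcds_length\tltr_identity\ttsd"]
    for n, c in enumerate(candidates, 1):
        lines.append(
            "\t".join(
                [
                    f"elem{n}",
                    c.contig_id,
                    str(c.elem_start),
                    str(c.elem_end),
                    str(c.total_len),
                    str(c.ltr5[1] - c.ltr5[0]),
                    str(c.internal[1] - c.internal[0]),
                    f"{c.ltr_identity:.4f}",
                    c.tsd,
                ]
            )
        )
    return "\n".join(lines) + "\n"
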