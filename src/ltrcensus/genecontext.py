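"""Mapping element consensi onto an annotated genome and calling context.

A retrotransposon consensus is aligned against the genome with a
seed-chain-extend local search; each surviving hit is then classified
against the gene models of its contig: exonic if it overlaps any exon by
at least one bp, intronic if it lies wholly inside a gene span without
touching an exon, intergenic otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable

from ltrcensus._seq import kmer_positions, revcomp
from ltrcensus.align import aligned_identity
from ltrcensus.synthgenome import Contig


@dataclass(frozen=True)
class GeneModel:
    """A gene as an exon list; coordinates 0-based half-open internally
    (GFF3 I/O converts from 1-based inclusive)."""

    gene_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        if ex != list(self.exons):
            raise ValueError("exons must be sorted")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id!r} has overlapping exons")
        for s, e in ex:
            if e <= s:
                raise ValueError("exon intervals must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


@dataclass(frozen=True)
class Hit:
    """One local alignment of the consensus on the genome."""

    contig_id: str
    start: int
    end: int
    strand: str
    aligned_len: int
    identity: float


@dataclass(frozen=True)
class InsertionCall:
    hit: Hit
    gene_id: str | None
    context: str  # exon | intron | intergenic

    @property
    def fragment_len(self) -> int:
        return self.hit.end - self.hit.start


def map_consensus_hits(
    consensus: str,
    genome: Iterable[Contig],
    min_len: int = 100,
    min_identity: float = 0.8,
    k: int = 13,
    max_seed_gap: int = 500,
) -> list[Hit]:
    """Seed-chain-extend local hits of the consensus on both genome strands.

    Word seeds are grouped on near-constant diagonals (split at seed gaps
    above ``max_seed_gap`` bp), extended with an X-drop walk, scored by
    global-alignment identity of the paired blocks, filtered by
    ``min_len``/``min_identity``, and reduced to non-overlapping best hits
    per locus (higher identity, then longer, then leftmost).
    """
    if len(consensus) < min_len:
        raise ValueError("consensus shorter than min_len")
    hits: list[Hit] = []
    for contig in genome:
        gindex = kmer_positions(contig.seq, k)
        for strand, query in (("+", consensus), ("-", revcomp(consensus))):
            seeds: list[tuple[int, int]] = []  # (diag, gpos)
            for qpos in range(len(query) - k + 1):
                for gpos in gindex.get(query[qpos : qpos + k], ()):
                    seeds.append((gpos - qpos, gpos))
            if not seeds:
                continue
            seeds.sort()
            groups: list[list[tuple[int, int]]] = [[seeds[0]]]
            for s in seeds[1:]:
                prev = groups[-1][-1]
                if s[0] - prev[0] <= 20 and abs(s[1] - prev[1]) <= max_seed_gap:
                    groups[-1].append(s)
                else:
                    groups.append([s])
            for grp in groups:
                diag = grp[len(grp) // 2][0]
                g0 = min(g for _, g in grp)
                g1 = max(g for _, g in grp) + k
                q0, q1 = g0 - diag, g1 - diag
                # X-drop extension of the genome/query block pair
                q0, g0 = _extend_pair(query, contig.seq, q0, g0, -1)
                q1, g1 = _extend_pair(query, contig.seq, q1 - 1, g1 - 1, +1)
                if g1 - g0 < min_len:
                    continue
                ident = aligned_identity(contig.seq[g0:g1], query[q0:q1])
                if ident < min_identity:
                    continue
                hits.append(
                    Hit(
                        contig_id=contig.id,
                        start=g0,
                        end=g1,
                        strand=strand,
                        aligned_len=g1 - g0,
                        identity=ident,
                    )
                )
    hits.sort(key=lambda h: (-h.identity, -h.aligned_len, h.contig_id, h.start))
    kept: list[Hit] = []
    for h in hits:
        if all(
            h.contig_id != o.contig_id or h.end <= o.start or h.start >= o.end
            for o in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: (h.contig_id, h.start))
    return kept


def _extend_pair(query: str, target: str, q: int, g: int, step: int, window: int = 50):
    """Maximum-likelihood boundary extension of a seed block.

    Scans up to `window` columns outward comparing query[q+t*step] with
    target[g+t*step], scoring match +1 / mismatch -1.6, and places the
    boundary at the global score maximum; a minimum gain of +3 is required
    before the edge moves at all, so chance matches in flanking sequence do
    not drag it outward.  Returns the new (q, g) bounds (half-open on the
    right for step=+1).
    """
    best, best_t = 2.0, 0
    score = 0.0
    for t in range(1, window + 1):
        pq, pg = q + t * step, g + t * step
        if pq < 0 or pg < 0 or pq >= len(query) or pg >= len(target):
            break
        score += 1.0 if query[pq] == target[pg] else -1.6
        if score > best:
            best, best_t = score, t
    if step < 0:
        return q - best_t, g - best_t
    return q + best_t + 1, g + best_t + 1


def classify_insertion(hit: Hit, genes: list[GeneModel]) -> InsertionCall:
    """Call the genic context of one hit.

    Exon overlap (>= 1 bp) takes precedence; otherwise a hit wholly inside
    a gene span is intronic; otherwise intergenic.  Only genes on the hit's
    contig are considered.
    """
    for gene in genes:
        if gene.contig_id != hit.contig_id:
            continue
        for s, e in gene.exons:
            if hit.start < e and s < hit.end:
                return InsertionCall(hit=hit, gene_id=gene.gene_id, context="exon")
    for gene in genes:
        if gene.contig_id != hit.contig_id:
            continue
        s, e = gene.span
        if s <= hit.start and hit.end <= e:
            return InsertionCall(hit=hit, gene_id=gene.gene_id, context="intron")
    return InsertionCall(hit=hit, gene_id=None, context="intergenic")


def summarize_contexts(
    calls: list[InsertionCall],
    is_chromosome: Callable[[str], bool] = lambda c: c.lower().startswith("chr"),
) -> dict[str, int]:
    """Partition counts over contexts and contig classes.

    Returns total hits, hits on chromosome-class vs scaffold-class contigs
    (by contig-id predicate), genic hits (exon or intron), and per-context
    counts; all partitions conserve the total.
    """
    ctx = Counter(c.context for c in calls)
    on_chrom = sum(1 for c in calls if is_chromosome(c.hit.contig_id))
    return {
        "total": len(calls),
        "chromosomal": on_chrom,
        "scaffold": len(calls) - on_chrom,
        "genic": ctx["exon"] + ctx["intron"],
        "exon": ctx["exon"],
        "intron": ctx["intron"],
        "intergenic": ctx["intergenic"],
    }


# ---------------------------------------------------------------------------
# GFF3 input and call output


def genes_from_gff3(path: str) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(g, featuretype="exon"))
        )
        if not exons:
            exons = ((g.start - 1, g.end),)
        genes.append(
            GeneModel(gene_id=g.id, contig_id=g.seqid, strand=g.strand, exons=exons)
        )
    return genes


def calls_to_tsv(calls: list[InsertionCall]) -> str:
    lines = ["contig\tstart\tend\tstrand\tfragment_len\tidentity\tcontext\tgene"]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.hit.contig_id,
                    str(c.hit.start),
                    str(c.hit.end),
                    c.hit.strand,
                    str(c.fragment_len),
                    f"{c.hit.identity:.4f}",
                    c.context,
                    c.gene_id or ".",
                ]
            )
        )
    return "\n".join(lines) + "\n"
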