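"""Synthetic genomes with planted LTR retrotransposons, reads and slot blots.

Every generator takes an explicit seed and is reproducible bit-for-bit.
The module emulates the three kinds of raw data a retrotransposon census
consumes:

* an assembled background genome carrying planted full-length elements
  (LTR + internal coding region + LTR, flanked by a target-site
  duplication) and solo LTRs, each copy independently mutated;
* uniform shotgun read sets with a per-base substitution error rate;
* slot-blot dilution ladders whose intensities are proportional to loaded
  target mass, with multiplicative log-normal noise.

Ground truth (exact coordinates and the untouched family templates) is
returned alongside the genome so downstream detection, clustering and
census stages can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ltrcensus._seq import check_dna, revcomp

BASES = np.array(list("ACGT"))


class CapacityError(RuntimeError):
    """Raised when planted copies cannot be placed without overlap."""


@dataclass(frozen=True)
class Contig:
    """A named assembled sequence over {A,C,G,T}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        check_dna(self.seq, f"contig {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FamilySpec:
    """Geometry and copy plan of one planted element family.

    A full-length copy is LTR + internal + LTR (total ``2*ltr_len +
    internal_len`` bp); a solo LTR is a single LTR, the footprint left
    behind after unequal recombination between an element's two repeats.
    ``divergence`` is the per-site substitution rate applied independently
    to every planted copy; ``tsd_len`` is the length of the target-site
    duplication created on insertion.
    """

    family_id: str
    ltr_len: int
    internal_len: int
    n_full: int
    n_solo: int
    divergence: float = 0.0
    tsd_len: int = 5

    def __post_init__(self) -> None:
        if self.ltr_len < 50:
            raise ValueError("ltr_len must be >= 50")
        if self.internal_len < 0:
            raise ValueError("internal_len must be >= 0")
        if self.n_full < 0 or self.n_solo < 0:
            raise ValueError("copy counts must be non-negative")
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must lie in [0, 0.5)")
        if not 0 <= self.tsd_len <= 10:
            raise ValueError("tsd_len must lie in [0, 10]")

    @property
    def total_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len


@dataclass(frozen=True)
class PlantedRecord:
    family_id: str
    contig_id: str
    start: int  # 0-based half-open, in the emitted genome
    end: int
    kind: str  # "full" | "solo"
    divergence_applied: float


@dataclass
class PlantedTruth:
    """Ground-truth ledger: planted intervals plus the unmutated templates."""

    records: list[PlantedRecord] = field(default_factory=list)
    templates: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (ltr, internal)

    def template_element(self, family_id: str, kind: str = "full") -> str:
        ltr, internal = self.templates[family_id]
        return ltr + internal + ltr if kind == "full" else ltr

    def planted_fraction(self, genome_len: int) -> float:
        return sum(r.end - r.start for r in self.records) / genome_len


@dataclass
class ReadSet:
    """Shotgun reads from one platform, all of one declared length."""

    platform_label: str
    reads: list[tuple[str, str]]
    read_len: int
    error_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        for _, seq in self.reads:
            if len(seq) != self.read_len:
                raise ValueError("all reads must have the declared length")

    @property
    def total_reads(self) -> int:
        return len(self.reads)


@dataclass
class DilutionSeries:
    """One slot-blot lane: intensities along a geometric dilution ladder.

    ``intensities[i]`` is the (arbitrary-unit) spot intensity of the sample
    diluted by ``base ** -exponents[i]`` relative to ``loaded_mass`` (ng for
    a plasmid standard, micrograms for genomic DNA) at exponent 0.
    """

    base: float
    exponents: list[int]
    intensities: list[float]
    loaded_mass: float

    def __post_init__(self) -> None:
        if len(self.exponents) != len(self.intensities):
            raise ValueError("one intensity per exponent required")
        if any(e < 0 for e in self.exponents):
            raise ValueError("exponents must be non-negative integers")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be non-negative")


# ---------------------------------------------------------------------------
# generators


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently at `rate` (never to the same base)."""
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([rng.choice(choices)])
    return arr.tobytes().decode()


def gen_background(length: int, gc: float, seed: int) -> Contig:
    """Draw a background contig of `length` i.i.d. bases with G+C fraction `gc`."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return Contig(id=f"bg_seed{seed}", seq=_random_seq(rng, length, gc))


def plant_families(
    genome: Contig,
    specs: list[FamilySpec],
    seed: int,
    min_gap: int = 0,
    max_attempts: int = 10_000,
) -> tuple[Contig, PlantedTruth]:
    """Insert all copies of several families at uniform non-overlapping sites.

    Insertion points are rejection-sampled in the coordinates of the input
    genome with pairwise spacing >= max(min_gap, tsd_len); each copy is
    independently mutated at its family's divergence and flanked by a
    duplicated target site.  Returns the emitted genome plus a truth ledger
    whose intervals are in emitted-genome coordinates.

    Planting several families in one call (rather than sequentially) keeps
    every copy of every family non-overlapping and every truth interval
    exact.
    """
    rng = np.random.default_rng(seed)
    host = genome.seq
    copies: list[tuple[FamilySpec, str]] = []
    for spec in specs:
        copies += [(spec, "full")] * spec.n_full + [(spec, "solo")] * spec.n_solo

    truth = PlantedTruth()
    for spec in specs:
        ltr = _random_seq(rng, spec.ltr_len)
        internal = _random_seq(rng, spec.internal_len)
        truth.templates[spec.family_id] = (ltr, internal)

    if not copies:
        return genome, truth

    max_tsd = max(spec.tsd_len for spec, _ in copies)
    spacing = max(min_gap, max_tsd, 1)
    lo, hi = max_tsd, len(host) - max_tsd
    if hi - lo < spacing * len(copies):
        raise CapacityError("genome too short for the requested copies")

    points: list[int] = []
    for _ in range(max_attempts):
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= spacing for q in points):
            points.append(p)
            if len(points) == len(copies):
                break
    else:
        raise CapacityError(
            f"placed only {len(points)}/{len(copies)} copies in {max_attempts} attempts"
        )

    order = sorted(range(len(copies)), key=lambda i: points[i])
    parts: list[str] = []
    prev = 0
    out_len = 0
    for idx in order:
        spec, kind = copies[idx]
        p = points[idx]
        template = truth.template_element(spec.family_id, kind)
        mutated = _mutate(template, spec.divergence, rng)
        tsd = host[p : p + spec.tsd_len]
        parts.append(host[prev:p])
        out_len += p - prev
        parts.append(tsd)
        out_len += len(tsd)
        start = out_len
        parts.append(mutated)
        out_len += len(mutated)
        truth.records.append(
            PlantedRecord(
                family_id=spec.family_id,
                contig_id=genome.id,
                start=start,
                end=out_len,
                kind=kind,
                divergence_applied=spec.divergence,
            )
        )
        prev = p  # host[p:p+tsd] reappears as the right-hand copy of the TSD
    parts.append(host[prev:])
    truth.records.sort(key=lambda r: r.start)
    return Contig(id=genome.id, seq="".join(parts)), truth


def plant_family(
    genome: Contig, spec: FamilySpec, seed: int, min_gap: int = 0
) -> tuple[Contig, PlantedTruth]:
    """Plant a single family; see :func:`plant_families`."""
    return plant_families(genome, [spec], seed, min_gap=min_gap)


def simulate_reads(
    genome: Contig,
    platform_label: str,
    read_len: int,
    n_reads: int,
    error_rate: float,
    seed: int,
) -> ReadSet:
    """Uniform shotgun reads from both strands with i.i.d. substitution errors."""
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    rng = np.random.default_rng(seed)
    seq = genome.seq
    reads: list[tuple[str, str]] = []
    if n_reads:
        starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for i, (s, rev) in enumerate(zip(starts, strands)):
            r = seq[s : s + read_len]
            if rev:
                r = revcomp(r)
            reads.append((f"{platform_label}_{i}", _mutate(r, error_rate, rng)))
    return ReadSet(
        platform_label=platform_label, reads=reads, read_len=read_len, error_rate=error_rate
    )


def simulate_slotblot(
    mass_fraction: float,
    exponents: list[int],
    base: float,
    loaded_mass: float,
    noise_cv: float,
    seed: int,
    gain: float = 1.0,
) -> DilutionSeries:
    """Slot-blot intensities for a geometric dilution ladder.

    Intensity at exponent e is ``gain * loaded_mass * mass_fraction *
    base**-e * eps`` with eps multiplicative log-normal noise of mean 1 and
    coefficient of variation ``noise_cv``.  ``mass_fraction`` is the target
    mass per unit loaded mass (e.g. insert ng per ng plasmid, or target ng
    per 1000 ng for genomic DNA loaded in micrograms).
    """
    if not 0 <= mass_fraction <= 1:
        raise ValueError("mass_fraction must lie in [0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    intensities = []
    for e in exponents:
        mean = gain * loaded_mass * mass_fraction * base ** (-e)
        if noise_cv > 0:
            sigma = math.sqrt(math.log(1 + noise_cv**2))
            mean *= math.exp(rng.normal(-sigma**2 / 2, sigma))
        intensities.append(mean)
    return DilutionSeries(
        base=base, exponents=list(exponents), intensities=intensities, loaded_mass=loaded_mass
    )


# ---------------------------------------------------------------------------
# writers


def write_fasta(contigs: list[Contig], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def write_reads(readset: ReadSet, path: str | Path, fmt: str = "fastq") -> None:
    """Write reads as FASTQ (constant quality 40) or FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for rid, seq in readset.reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> None:
    """BED-like TSV (0-based half-open): contig, start, end, family, kind, divergence."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tfamily\tkind\tdivergence\n")
        for r in truth.records:
            fh.write(
                f"{r.contig_id}\t{r.start}\t{r.end}\t{r.family_id}\t{r.kind}\t"
                f"{r.divergence_applied}\n"
            )


def write_manifest(path: str | Path, seed: int, specs: list[FamilySpec], **extra) -> None:
    payload = {
        "seed": seed,
        "families": [
            {
                "family_id": s.family_id,
                "ltr_len": s.ltr_len,
                "internal_len": s.internal_len,
                "n_full": s.n_full,
                "n_solo": s.n_solo,
                "divergence": s.divergence,
                "tsd_len": s.tsd_len,
            }
            for s in specs
        ],
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
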