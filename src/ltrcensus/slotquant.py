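"""Slot-blot dilution-standard copy-number calculus.

A slot blot loads serial dilutions of a plasmid standard (known insert
mass) and of genomic DNA side by side and hybridises both with the same
probe.  Spot intensity is proportional to target mass, so the pair of
dilution steps with matching intensity fixes the target mass per microgram
of genomic DNA:

    ng/ug  =  insert_ng * base^-e_p / (gdna_ug * base^-e_g)

Multiplying by genome size converts that mass fraction into target bp per
genome, and dividing by the probed segment length gives the copy number.
Comparing LTR-probe and CDS-probe copy numbers then reads out element
integrity: an intact element carries two LTRs per coding region, so a
ratio near 2 means mostly full-length copies, a larger ratio means an
excess of solo LTRs (recombination relics), and a smaller one an LTR
deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ltrcensus._seq import round_half_up
from ltrcensus.synthgenome import DilutionSeries


class MatchingError(ValueError):
    """No usable intensity pair to match between two dilution series."""


@dataclass(frozen=True)
class PlasmidStandard:
    """Plasmid standard: vector plus probed insert, total mass in ng."""

    total_mass: float
    insert_len: int
    vector_len: int

    def __post_init__(self) -> None:
        if self.total_mass <= 0 or self.insert_len <= 0 or self.vector_len < 0:
            raise ValueError("plasmid standard dimensions must be positive")


@dataclass(frozen=True)
class GenomeSpec:
    species: str
    genome_bp: float
    c_value_pg: float | None = None

    def __post_init__(self) -> None:
        if self.genome_bp <= 0:
            raise ValueError("genome_bp must be positive")


@dataclass(frozen=True)
class CopyEstimate:
    species: str
    segment: str
    segment_len: int
    ng_per_ug: float
    target_bp: float
    copies: int

    @property
    def mb_per_genome(self) -> float:
        return self.target_bp / 1e6


@dataclass(frozen=True)
class RatioReport:
    ratio: float
    solo_ltr_estimate: int
    flag: str  # mostly_full_length | solo_ltr_excess | ltr_deficit


def insert_mass(std: PlasmidStandard) -> float:
    """ng of insert in the loaded plasmid: total mass times the insert's
    share of the plasmid length."""
    return std.total_mass * std.insert_len / (std.insert_len + std.vector_len)


def match_dilution(plasmid: DilutionSeries, gdna: DilutionSeries) -> tuple[int, int]:
    """Exponent pair (e_plasmid, e_gdna) with the most similar intensities.

    Similarity is measured in log space because dilution ladders are
    geometric.  Zero intensities are excluded; ties resolve to the smallest
    plasmid exponent, then the smallest genomic exponent.
    """
    best: tuple[float, int, int] | None = None
    for ep, ip in zip(plasmid.exponents, plasmid.intensities):
        if ip <= 0:
            continue
        for eg, ig in zip(gdna.exponents, gdna.intensities):
            if ig <= 0:
                continue
            d = abs(math.log(ip) - math.log(ig))
            key = (d, ep, eg)
            if best is None or key < best:
                best = key
    if best is None:
        raise MatchingError("no non-zero intensity pair to match")
    return best[1], best[2]


def ng_per_ug(
    insert_ng: float, factor_p: float, factor_g: float, gdna_loaded: float
) -> float:
    """Target mass (ng) per microgram of genomic DNA from a matched pair.

    ``factor_p`` and ``factor_g`` are the residual dilution factors of the
    matched slots (e.g. 3**-2 and 3**-1); ``gdna_loaded`` is the undiluted
    genomic load in micrograms.
    """
    if not 0 < factor_p <= 1 or not 0 < factor_g <= 1:
        raise ValueError("dilution factors must lie in (0, 1]")
    if gdna_loaded <= 0:
        raise ValueError("gdna_loaded must be positive")
    return insert_ng * factor_p / (gdna_loaded * factor_g)


def copies_per_genome(
    ng_per_ug_value: float, genome: GenomeSpec, segment_len: int, segment: str = ""
) -> CopyEstimate:
    """Convert ng target per ug genomic DNA into bp and copies per genome.

    ng/ug times 1e-3 is a dimensionless mass fraction; times genome size it
    is target bp per genome; divided by the probed segment length and
    rounded half-up it is the copy number.
    """
    if ng_per_ug_value < 0 or segment_len <= 0:
        raise ValueError("ng_per_ug must be >= 0 and segment_len positive")
    target_bp = ng_per_ug_value * 1e-3 * genome.genome_bp
    return CopyEstimate(
        species=genome.species,
        segment=segment,
        segment_len=segment_len,
        ng_per_ug=ng_per_ug_value,
        target_bp=target_bp,
        copies=round_half_up(target_bp / segment_len),
    )


def interpret_ltr_cds(copies_ltr: int, copies_cds: int, tol: float = 0.25) -> RatioReport:
    """Read element integrity off the LTR:CDS copy-number ratio.

    An intact element contributes two LTRs per coding region, so ratio ~ 2
    (within 2*tol) flags mostly full-length copies; above that, a solo-LTR
    excess from unequal recombination; below, an LTR deficit.  The solo-LTR
    estimate is the LTR count unexplained by intact elements,
    max(copies_ltr - 2*copies_cds, 0).
    """
    if copies_cds <= 0:
        raise ValueError("copies_cds must be positive")
    ratio = copies_ltr / copies_cds
    if ratio > 2 * (1 + tol):
        flag = "solo_ltr_excess"
    elif ratio < 2 * (1 - tol):
        flag = "ltr_deficit"
    else:
        flag = "mostly_full_length"
    return RatioReport(
        ratio=ratio,
        solo_ltr_estimate=max(copies_ltr - 2 * copies_cds, 0),
        flag=flag,
    )


def fold_change(copies_a: int, copies_b: int) -> float:
    """Copy-number ratio a/b (report rounded to the nearest integer)."""
    if copies_b <= 0:
        raise ValueError("copies_b must be positive")
    return copies_a / copies_b


# ---------------------------------------------------------------------------
# whole-survey table


def copy_number_table(
    genomes: list[GenomeSpec],
    ng_per_ug_measured: dict[str, dict[str, float]],
    segment_lens: dict[str, int],
) -> pd.DataFrame:
    """Recompute the full survey table from measured ng/ug values.

    ``ng_per_ug_measured`` maps segment label (e.g. "Orchid-rt1-LTR") to
    {species: ng/ug}; returns one row per (segment, species) with the
    ng/ug input and the derived Mb/genome and copies/genome.
    """
    by_species = {g.species: g for g in genomes}
    rows = []
    for segment, per_species in ng_per_ug_measured.items():
        seg_len = segment_lens[segment]
        for species, value in per_species.items():
            est = copies_per_genome(value, by_species[species], seg_len, segment)
            rows.append(
                {
                    "segment": segment,
                    "species": species,
                    "ng_per_ug": value,
                    "mb_per_genome": round(est.mb_per_genome, 3),
                    "copies_per_genome": est.copies,
                }
            )
    return pd.DataFrame(rows)
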