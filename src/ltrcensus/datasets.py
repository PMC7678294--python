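"""Bundled example dataset: a four-species Phalaenopsis orchid LTR survey.

These are the measured inputs of a published-style survey of four
gypsy-like retrotransposons (Orchid-rt1 and Gypsy1-3) across four
Phalaenopsis orchid genomes: genome sizes, plasmid standard geometry,
slot-blot ng/ug readouts, probed segment lengths, and raw-read census
counts for three sequencing datasets (Roche 454, BAC-end sequences, and
Illumina).  They serve as worked-example inputs for the slot-blot and
read-census calculi; everything downstream (Mb per genome, copy numbers,
fractions, ratios) is computed, not stored.
"""

from __future__ import annotations

from ltrcensus.slotquant import GenomeSpec, PlasmidStandard

#: Genome sizes (bp) and 1C values (pg) of the four surveyed species.
GENOMES = [
    GenomeSpec("P. equestris", 1.6e9, c_value_pg=2.95),
    GenomeSpec("P. aphrodite", 1.52e9, c_value_pg=2.8),
    GenomeSpec("P. violacea", 6.99e9, c_value_pg=12.89),
    GenomeSpec("P. bellina", 7.07e9, c_value_pg=13.04),
]

#: Plasmid standards: 10 ng total, probed insert cloned into a 3015-bp vector.
PLASMID_STANDARDS = {
    "Orchid-rt1-LTR": PlasmidStandard(total_mass=10.0, insert_len=707, vector_len=3015),
    "Orchid-rt1-CDS": PlasmidStandard(total_mass=10.0, insert_len=5121, vector_len=3015),
}

#: Probed segment lengths (bp) per slot-blot probe.
SEGMENT_LENS = {
    "Orchid-rt1-LTR": 707,
    "Orchid-rt1-CDS": 5121,
    "Gypsy1-LTR": 1722,
    "Gypsy1-CDS": 5110,
    "Gypsy2-LTR": 1720,
    "Gypsy3-LTR": 1641,
}

#: Slot-blot readout: ng of probed target per ug genomic DNA, per species.
NG_PER_UG = {
    "Orchid-rt1-LTR": {
        "P. equestris": 0.63,
        "P. aphrodite": 1.9,
        "P. violacea": 1.9,
        "P. bellina": 1.9,
    },
    "Orchid-rt1-CDS": {
        "P. equestris": 6.3,
        "P. aphrodite": 6.3,
        "P. violacea": 6.3,
        "P. bellina": 6.3,
    },
    "Gypsy1-LTR": {
        "P. equestris": 1.2,
        "P. aphrodite": 3.6,
        "P. violacea": 10.8,
        "P. bellina": 10.8,
    },
    "Gypsy1-CDS": {
        "P. equestris": 0.7,
        "P. aphrodite": 2.1,
        "P. violacea": 6.3,
        "P. bellina": 6.3,
    },
    "Gypsy2-LTR": {
        "P. equestris": 3.6,
        "P. aphrodite": 10.8,
        "P. violacea": 3.6,
        "P. bellina": 3.6,
    },
    "Gypsy3-LTR": {
        "P. equestris": 3.5,
        "P. aphrodite": 1.17,
        "P. violacea": 3.5,
        "P. bellina": 3.5,
    },
}

#: Raw-read census of the six high-copy repeats: element length (bp) and
#: read counts in each of the three datasets.
READ_CENSUS_COUNTS = {
    "Orchid-its16S": {"size": 2060, "454": 1625, "BES": 345, "Illumina": 20_914},
    "Orchid-mite1": {"size": 317, "454": 500, "BES": 30, "Illumina": 664},
    "Orchid-rt-anc1": {"size": 3396, "454": 6961, "BES": 764, "Illumina": 59_493},
    "Orchid-rt1": {"size": 12_754, "454": 57_245, "BES": 2927, "Illumina": 358_553},
    "Orchid-rt2": {"size": 3059, "454": 4650, "BES": 247, "Illumina": 41_109},
    "Orchid-rt3": {"size": 3410, "454": 17_457, "BES": 1999, "Illumina": 112_842},
}

#: Total reads per dataset.
READ_TOTALS = {"454": 439_604, "BES": 18_486, "Illumina": 3_354_752}

#: Geometry of the highest-copy element, Orchid-rt1: 707-bp LTRs flanking a
#: 5121-bp coding region inside a 12,671-bp full-length element.
ORCHID_RT1 = {"ltr_len": 707, "cds_len": 5121, "total_len": 12_671}

#: Aggregate genome share of Orchid-rt1 estimated from the read census.
ORCHID_RT1_GENOME_FRACTION = 0.138
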