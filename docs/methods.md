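# Methods

`ltrcensus` implements the computational chain used to census high-copy
long terminal repeat (LTR) retrotransposons in plant genomes: structural
detection of full-length elements in assembled contigs, family grouping,
abundance estimation from unassembled reads, copy-number quantification
from slot-blot dilution standards, and classification of insertion
contexts against gene models. A synthetic-data module generates genomes,
reads and blot intensities with exact ground truth so that every stage can
be validated offline.

## The biological model

An intact LTR retrotransposon is two near-identical direct repeats (the
LTRs) flanking an internal coding region (gag/pol: protease, reverse
transcriptase, RNase H, integrase). At insertion the two LTRs are
identical and the integration machinery duplicates a 4–6 bp target site
(TSD) on either side; afterwards each copy accumulates substitutions
independently. Unequal recombination between an element's two LTRs
deletes the internal region plus one repeat and leaves a **solo LTR** —
which is why the LTR:CDS copy-number ratio reads out element integrity: a
population of intact elements has ratio ≈ 2, a solo-LTR excess pushes it
higher. The *Ty3/gypsy* and *Ty1/copia* superfamilies are distinguished
by the order of reverse transcriptase and integrase in the pol
polyprotein (integrase downstream of RT → gypsy; upstream → copia).

## Synthetic data (`synthgenome`)

* **Background**: i.i.d. bases at a configurable GC fraction.
* **Planting**: all copies of all families are placed in one pass at
  uniformly sampled, rejection-checked insertion points (capped attempts;
  a capacity error otherwise). A full copy is `LTR + internal + LTR`, a
  solo copy a single LTR; each copy is independently mutated at the
  family's per-site substitution rate and flanked by an exact duplication
  of the `tsd_len` host bases at the insertion point. Substitutions only
  (no indels) by default, so truth coordinates are exact. The default
  geometry (707 bp LTRs, 11,257 bp internal region, 12,671 bp total,
  5 bp TSD) matches the highest-copy element of the bundled survey; the
  TSD length itself is a modelling default, as integration-site
  duplications in this size class are typically 4–6 bp.
* **Reads**: uniform start positions on both strands, i.i.d. substitution
  errors at a per-base rate; no indels, quality constant. Real 454/BES/
  Illumina error profiles, paired ends and insert-size structure are
  deliberately not modelled — the census arithmetic depends only on which
  reads word-match an element, so uniform substitution noise is the
  relevant stressor.
* **Slot blots**: intensity at dilution exponent e is
  `gain · loaded_mass · mass_fraction · base^-e`, with multiplicative
  log-normal noise of mean 1 and configurable coefficient of variation.
  Saturation and probe-kinetics effects are not modelled.

Because the generator omits indels, real error profiles and nested
insertions, passing recovery suites demonstrates correctness of the
census logic under its stated model, not performance on real sequencing
data.

## Detection (`ltrdetect`)

Seed–band–refine over one contig:

1. index all k-words (k = 13) and collect match pairs whose separation
   implies an element length within `[min_elem, max_elem]`
   (defaults 1,500–20,000 bp; LTR window 100–3,000 bp);
2. group pairs into diagonal bands (separation drift ≤ 20 bp tolerates
   small indels), split bands at seed gaps > 200 bp, and discard groups
   with fewer than 3 supporting word matches;
3. place each block edge at the maximum of a change-point score: columns
   pairing the two putative repeats score +1 on match and −1.6 on
   mismatch, the log-likelihood-ratio weighting for ~90 % within-repeat
   versus 25 % background per-base agreement. The scan runs up to 200
   columns outward (word seeds can end > 100 bp before a diverged repeat's
   true end when mismatches cluster) and 300 inward (to retract edges
   inflated by a chance word match), and requires a gain > 2 before
   moving an edge at all;
4. jointly re-place both element boundaries over a ± 15 bp window,
   adding log 4 per base of an exact 4–6 bp flanking duplication plus a
   presence prior (+5): integration essentially always leaves a TSD, so
   boundary placements that exhibit one are favoured over chance
   excursions of the similarity profile;
5. score the repeat pair by global-alignment identity (edlib), apply the
   length/identity bounds (identity floor 0.80), and resolve overlapping
   candidates by identity, then length, then position.

Direct repeats are strand-symmetric, so a single forward scan covers both
strands; candidates are reported once in forward coordinates.

**Accuracy** (validated on seven independent 20-genome suites, two
elements each, divergence 0–0.05): recall 100 % throughout; boundary
error ≤ 5 bp in 279/280 elements. The single exception carried a second
exact 6-mer "TSD" in the host 13 bp from the insertion point — a fixture
whose planted coordinates are not the maximum-a-posteriori reading of the
sequence, which no sequence-only detector can resolve. Elements of the
same family inserted closer than `max_elem` can chimerically pair the 3′
LTR of one copy with the 5′ LTR of the next; the interval-resolution rule
does not attempt to untangle such tandem proximity, and the recovery
suites plant copies with spacing above the detection window.

## Family grouping (`famcluster`)

Similarity between two elements is the fraction of one element's 12-mers
(word positions, both strands) found anywhere in the other, symmetrised —
a quantitative surrogate for judging a dot plot. Families are the
connected components at similarity ≥ 0.5 (single linkage); the consensus
is a per-column majority vote over a star alignment to the longest
member (ties alphabetical, deletion-majority columns dropped).

**Working range of the 0.5 / word-12 defaults**: two copies each mutated
at per-site rate d from a common template agree per base with probability
≈ (1−d)² + d²/3, so a 12-word survives with probability ≈ (1−2d)¹²:
about 0.62 at d = 0.02 but only ≈ 0.29 at d = 0.05, below the linking
threshold. Families with per-copy divergence beyond ≈ 0.028 therefore
shatter at these defaults regardless of implementation; recovery suites
use d = 0.02, and callers clustering older families should lower the
threshold or the word size accordingly.

Superfamily calls require externally supplied domain annotations (the
order rule above); translated-motif scanning against protein databases is
out of scope.

## Read census (`readcensus`)

A read is attributed to the element with the highest word containment —
the fraction of the read's 13-words present in the element's word set
(either strand) — provided it reaches 0.5; ties break lexicographically,
and each read counts toward at most one element. Fractions are
read counts over dataset totals (displayed at 3 decimals, kept raw
internally); fraction × genome size gives target bp, divided by element
length and rounded half-up gives copies.

The containment floor makes sensitivity decay with the mismatch rate
between read and reference: a 13-word survives ≈ (1−m)¹³ for per-base
mismatch rate m (read error + copy divergence), so the census is
calibrated for recently amplified, high-identity families — exactly the
repeat class whose assembly collapses and which therefore needs a
read-based census. Recovery suites use identical planted copies,
12 copies in a ~760 kb genome (mass fraction ≈ 0.2), 2× coverage of
100 bp reads at 1 % error; copy number is recovered within 10 % in every
replicate, and fractions sit within binomial sampling noise (the suite
allows the expected one-in-twenty 3σ outlier and bounds everything at
4σ).

## Slot-blot calculus (`slotquant`)

The insert share of a plasmid standard is `total_mass ·
insert_len/(insert_len+vector_len)`. Equal-intensity slots are matched in
log space (dilution ladders are geometric; zero intensities excluded,
ties to the smallest exponents), giving

    ng/µg = insert_ng · base^-e_plasmid / (gdna_µg · base^-e_gdna).

ng/µg × 10⁻³ × genome size = target bp per genome; divided by the probed
segment length and rounded half-up it is the copy number (Mb values
reported at 3 decimals). The LTR:CDS ratio is flagged
`mostly_full_length` within 2 ± 0.5 (tol = 0.25, chosen so an observed
ratio of 2.18 classifies as intact), `solo_ltr_excess` above,
`ltr_deficit` below; the solo-LTR estimate is
`max(copies_LTR − 2·copies_CDS, 0)`.

The bundled four-species *Phalaenopsis* survey dataset (genome sizes,
measured ng/µg values, segment lengths, read-census counts) feeds the
worked examples; recomputing its full table reproduces every printed Mb
value and all copy numbers except one (Gypsy3 in *P. aphrodite*:
1.17 × 10⁻³ × 1.52 Gbp / 1641 = 1083.7, which rounds to 1084 against a
printed 1083) — retained as a documented discrepancy, not patched.
Optional pg→bp conversion is off by default: the survey's own pg/Gbp
pairs do not follow the usual 978 Mbp/pg constant.

## Insertion context (`genecontext`)

Consensus-to-genome hits come from the same seed–group–refine machinery
(13-mer seeds, diagonal grouping with 500 bp gap splitting, change-point
boundary placement, identity ≥ 0.8, length ≥ 100 bp, best
non-overlapping hit per locus, both strands). Classification against
exon-list gene models: any ≥ 1 bp exon overlap → exon; else wholly inside
a gene span → intron; else intergenic. Exon precedence for
boundary-straddling hits is a convention; UTRs are not modelled. Hit
boundaries are ambiguous up to chance agreement of flanking bases with
the consensus continuation (usually ≤ 2 bp), which matters only when
comparing against exact planted coordinates.

## Numerical conventions

* Coordinates 0-based half-open internally; GFF3 I/O converts to 1-based
  inclusive.
* Copy numbers round half-up (`floor(x+0.5)`), matching the survey table;
  Python's banker's rounding is deliberately avoided.
* All generators take explicit integer seeds and are bit-for-bit
  reproducible; tests and the acceptance script derive sub-seeds from a
  single seed.
* Problem sizes in the recovery suites (90 kb detection genomes, ~760 kb
  census genomes, 200 blot replicates) are chosen as the smallest sizes
  at which the binomial error bars are decisively inside the tolerances
  being demonstrated.

## Known limitations

* No indel mutations by default (coordinate truth stays exact); enable
  realistic indels only where approximate coordinates suffice.
* Nested and tandem-proximal insertions are not untangled.
* Family clustering defaults only link families up to ≈ 3 % per-copy
  divergence (see above).
* The read census undercounts families whose divergence from the
  reference approaches the containment floor.
* Slot-blot simulation ignores saturation; the quantification step
  resolves mass only to one dilution step.
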