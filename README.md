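# ltrcensus

A census toolkit for **LTR retrotransposons** — the class I transposable
elements, flanked by two long terminal repeats (LTRs), whose amplification
drives most of the genome-size variation among plants. The package was
built around the kind of survey done for *Phalaenopsis* orchids, where a
handful of gypsy-like families (one of them spanning ~14 % of the genome)
account for a multi-gigabase difference between related species, but every
stage is generic and works on any assembled contigs, shotgun read sets and
hybridisation readouts.

It covers five questions, each as an importable module with a thin CLI
subcommand on top:

| stage | module | question |
| --- | --- | --- |
| structural detection | `ltrdetect` | where are full-length elements (two near-identical terminal repeats at element-scale separation, plus target-site duplication)? |
| family grouping | `famcluster` | which elements belong together; what is each family's consensus; gypsy or copia? |
| read census | `readcensus` | what fraction of the raw reads — and hence of the genome — does each family occupy, and how many copies is that? |
| slot-blot calculus | `slotquant` | how many copies per genome follow from a dilution-standard hybridisation, and what does the LTR:CDS ratio say about solo LTRs? |
| insertion context | `genecontext` | where do copies sit relative to gene models: exon, intron or intergenic? |

A sixth module, `synthgenome`, generates background genomes with planted
element families (known coordinates, divergence and TSDs), shotgun reads
with substitution errors, and slot-blot dilution ladders with
multiplicative noise — the ground truth against which the whole pipeline
is tested.

## The arithmetic at the core

For a repeat family with element length *L* in a genome of size *G*:

* **read census**: if a fraction *f* of all sequenced reads word-match the
  family, the family occupies *f·G* bp ≈ *f·G/L* copies;
* **slot blot**: if the plasmid standard (insert mass *m* ng) diluted
  *b*⁻ᵉᵖ matches the intensity of 1 µg genomic DNA diluted *b*⁻ᵉᵍ, the
  target mass is *m·b*⁻ᵉᵖ⁺ᵉᵍ ng/µg; times 10⁻³·*G* it is bp per genome,
  over the probed segment length it is copies;
* **integrity**: intact elements carry two LTRs per coding region, so
  copies(LTR)/copies(CDS) ≈ 2 means mostly full-length elements, ≫ 2 an
  excess of solo LTRs left by unequal recombination, and
  max(LTR − 2·CDS, 0) estimates the solo-LTR count.

## Worked example

Simulate a genome with a planted family (707 bp LTRs, 11,257 bp internal
region — two full copies and one solo LTR at 1 % divergence), then detect:

```bash
$ ltrcensus simulate --length 80000 --seed 11 --n-full 2 --n-solo 1 \
    --divergence 0.01 --reads illumina:100:1000:0.01 --out sim/
wrote genome (106064 bp), 3 planted copies -> sim

$ ltrcensus detect sim/genome.fa --tsv elems.tsv --elements-fasta elems.fa
2 candidate element(s)

$ cat elems.tsv
element  contig     start  end    total_length  ltr_length  cds_length  ltr_identity  tsd
elem1    bg_seed11  53107  65777  12670         706         11258       0.9688        ACATAT
elem2    bg_seed11  70097  82767  12670         706         11258       0.9745        AGACAG
```

Both full-length copies are recovered at (here, within 1 bp of) their
planted coordinates with the expected repeat identity for 1 % per-copy
divergence (~(1−0.01)² ≈ 0.98 before alignment effects); the solo LTR is
correctly *not* called a full-length element. Clustering (`ltrcensus
cluster`) groups the two into one family and writes its consensus;
`ltrcensus census` then counts reads against that consensus.

The slot-blot subcommand recomputes the bundled four-species orchid
survey from its measured ng/µg readouts:

```bash
$ ltrcensus slotblot --out survey.tsv
24 estimates written -> survey.tsv

$ head -4 survey.tsv
segment         species       ng_per_ug  mb_per_genome  copies_per_genome
Orchid-rt1-LTR  P. equestris  0.63       1.008          1426
Orchid-rt1-LTR  P. aphrodite  1.9        2.888          4085
Orchid-rt1-LTR  P. violacea   1.9        13.281         18785
```

Read as: 0.63 ng of LTR target per µg of *P. equestris* genomic DNA ×
1.6 Gbp genome = 1.008 Mbp of LTR sequence ≈ 1426 copies of the 707 bp
repeat; the same probe in the 7 Gbp *P. violacea* genome gives ~18,800
copies — the copy-number expansion that tracks genome size.

See `docs/methods.md` for the models, defaults and their rationale.

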