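# polyprime

Genome-specific PCR primer design for homoeologous genes in allopolyploids.

In an allopolyploid such as bread wheat (*Triticum aestivum*, genomes
A/B/D), each gene exists as two or more homoeologous copies that are
nearly identical in exons (>95% coding identity) but divergent in introns
(~69–82% identity). Amplifying *one* copy — for sequence-diversity
surveys, association mapping, or null-allele diagnostics — requires
primers that discriminate between copies. `polyprime` automates the
strategy that works at the bench:

1. **Align** the homoeologous genomic sequences and label every alignment
   column exon / intron / junction.
2. **Find discriminative sites**: columns where the target copy's residue
   differs from *every* other copy (SNPs), or edges of indels private to
   the target, preferentially in introns.
3. **Anchor primers** with their 3′-terminal base on such a site, then
   grow or trim the 5′ end until the nearest-neighbor melting temperature
   falls in a target window (default 59–61 °C, length 16–25 nt), and apply
   composition filters (GC 30–70%, homopolymers, self-dimers).
4. **Validate in silico** with a mismatch-position-aware PCR model: a
   3′-terminal mismatch blocks extension (`NONE`), a mismatch at positions
   2–5 from the 3′ end still primes weak amplification (`WEAK`), anything
   further in is tolerated (`STRONG`). A pair is genome-specific iff it
   yields exactly one STRONG product on its own copy and no STRONG *or*
   WEAK product on any homoeolog.
5. **Tile** the gene with amplicons of ~800–1500 bp overlapping by
   ~80–100 bp (so Sanger reads assemble into one contig), maximizing union
   coverage exactly, and report per-genome coverage.
6. **Type null alleles**: presence/absence of diagnostic products
   classifies wild type, single, double and triple deletion nulls (type
   codes 1–8), as used for the wheat waxy (*Wx*) loci.

The package ships the published wheat *Wx*/*SSII* genome-specific primer
panel (GenBank AB019622–AB019624, AB201445–AB201447) as a regression
input, and a seeded simulator of homoeolog families (exon/intron
divergence structure, intron indels, deletion nulls) so the whole pipeline
is testable without downloads.

## Worked example

```bash
polyprime simulate --seed 11 --out demo/sim
polyprime design demo/sim/family.fa demo/sim/family.gff3 \
    --alignment demo/sim/alignment.fa --out demo/design
```

prints the per-genome coverage table:

```
genome  n_pairs  covered_bp  gene_length  coverage_pct
    G1        3        3791         3934          96.4
    G2        3        3726         3867          96.4
    G3        3        3721         3887          95.7
```

i.e. for each simulated genome copy the tiler selected three
genome-specific primer pairs whose amplicons jointly cover ~96% of the
~3.9-kb gene. `demo/design/primers.tsv` lists the primers in a
publication-style layout (name, sequence 5′→3′, annealing °C, product
size, genome, 1-based coordinates, Tm):

```
primer_name  sequence_5to3           annealing_C  size_bp  genome  start_1based  end_1based  tm_C
G1-F1        GCGTCTACTAGCGTTTGTTC    60.0         1449     G1      9             28          61.0
G1-R1        TTCCTATTCGCTCTGATAAAGG  60.0         1449     G1      1436          1457        59.3
```

`demo/design/amplicons.bed` holds the products (0-based half-open) and
`report.json` the stage counts (sites → candidates → specific pairs →
tiled). `polyprime validate primers.tsv family.fa` re-scores any primer
table against a template set, and `polyprime type panel.tsv alleles.fa`
genotypes samples from allele sequences.

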