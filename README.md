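# gme-tools

Global microsatellite enrichment (GME) toolkit: design of a capture bait
set targeting every 1–6-mer tandem-repeat motif, and the downstream
analysis pipeline that turns unmapped sequencing reads into novel,
cross-sample-concordant contigs with k-mer family statistics.

## What it does

- **`gme.motif_families`** — canonical repeat-motif families: equivalence
  classes of 1–6-mer motifs under cyclic rotation and reverse
  complementation, named by their lexicographically smallest member.
- **`gme.bait_design`** — the full bait set: 120-nt baits of four 30-nt
  tandem-fill segments covering all 501 primitive families, balanced
  toward 40% G+C per bait and selected for low hairpin potential.
- **`gme.read_prep`** — sliding-window quality trimming (window 10,
  Q20, length floor 70) and N filtering (floor 50) of FASTQ reads.
- **`gme.repeat_finder`** — tandem-repeat detection for periods 1–6
  with wraparound-alignment scoring (match +2, mismatch −7, indel −5,
  minimum score 14), plus an exhaustive brute-force oracle used by the
  tests.
- **`gme.concordance`** — known/novel contig classification against
  reference sets, Velvet-style contig ID parsing, coverage→depth
  conversion (`C = Ck·L/(L−k+1)`), concordant grouping of novel contigs
  across samples (ungapped, ≤0/1 mismatch over >70% of the query),
  star-alignment consensus, cDNA extraction from multi-exon
  annotations, and perfect-match read counting.
- **`gme.stats_depth`** — family-by-sample depth tables, period-class
  fraction profiles, fold-enrichment ratios, motif prevalence.
- **`gme.synthetic_data`** — a seeded simulator (reference genome with
  planted repeat loci, extra-referential pentamer segments with unique
  flanks, 150-base paired-end DNA reads, 75-base RNA-like reads) plus a
  naive substitution mapper and a greedy exact-overlap assembler so the
  whole pipeline runs offline.
- **`gme.pipeline`** — end-to-end orchestration and planted-locus
  recovery scoring.

## CLI

```sh
gme design-baits --gc-target 0.40 --gc-tol 0.05 --min-loop 3 --seed 1 -o baits.fa
gme trim --window 10 --q 20 --min-len 70 in.fastq out.fastq
gme nfilter --min-len 50 in.fastq out.fastq
gme find-repeats contigs.fa -o hits.tsv
gme classify --known ref.fa contigs.fa -o status.tsv
gme concord --max-mismatch 1 s1.novel.fa s2.novel.fa -o groups.tsv
gme match-reads queries.fa reads1.fastq reads2.fastq -o matrix.tsv
gme cdna contigs.fa exons.gff -o cdna.fa
gme simulate --seed 5 --samples 2 -o simdir/
```

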