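# ecckit

Downstream characterization and differential analysis of
**extrachromosomal circular DNA** (eccDNA) from Circle-seq experiments.

Circle-seq enriches circular DNA (exonuclease digestion of linear DNA
followed by rolling-circle amplification), and callers such as
Circle-Map report each detected circle as a genomic interval with
per-sample read counts. `ecckit` takes those interval calls — not raw
reads — and computes the standard descriptive and comparative analyses
of an eccDNA study comparing two donor groups (e.g. young vs old
adipose-derived stem cells):

- **Abundance, GC content, size distribution** per sample and group:
  medians, 75th percentiles, fraction of circles < 1 kb, multi-modal
  size peaks from a smoothed histogram, Wilcoxon rank-sum group
  comparisons.
- **Chromosomal density**: circles per megabase per chromosome and its
  Pearson correlation with protein-coding gene and Alu element density.
- **Element enrichment** by *normalized genomic coverage*: for a class
  of elements C (exon, intron, UTRs, 2 kb gene flanks, CpG islands,
  Alu),

  ```
  ratio(C) = % of molecules whose start position lies in C
             ─────────────────────────────────────────────
             % of genome bases covered by (merged) C
  ```

  so ratio = 1 means no enrichment over uniform starts. Repeat classes
  (satellite, LINE, SINE, LTR, DNA, simple repeat) are scored as the
  percent of eccDNA reads whose interval overlaps the class.
- **Junction motifs**: 10 bp up/downstream reference sequence at every
  circle's start and end coordinate, per-position nucleotide and
  trinucleotide frequencies against the genome-wide trinucleotide
  background, and a scan for a pair of identical trinucleotides
  separated by a fixed spacer flanking the junction.
- **Differential eccDNA calling** on pooled group counts with a
  two-proportion z-test (the binomial sampling null targeted by
  MA-plot random-sampling methods for grouped libraries),
  Benjamini–Hochberg q-values, and the significance rule
  |fold change| ≥ 2 **and** q < 0.001.
- **Conjoint analysis**: differential eccDNAs mapped to host genes
  (any overlap with gene body ± 2 kb) and intersected with a
  differential-mRNA table, requiring the same direction of change.

A first-class **synthetic-data generator** produces toy genomes,
element annotations, eccDNA populations, and count matrices with known
ground truth (planted size modes, start-position enrichment, junction
motifs, fold changes), so every stage is testable without any download.

## Worked example

Run the bundled synthetic demonstration (simulates a 4 Mb, 4-chromosome
genome and a 2000-circle population across 3 + 3 samples, then runs all
stages):

```
ecckit run --seed 7 --outdir ecckit_out
```

`ecckit_out/report.json` then contains, among others (seed 7):

- `characterize.groups.young`: 6000 records across the three young
  samples, GC mean 43.0%, median length 417 bp, p75 785 bp, 98.2% of
  circles < 1 kb, size peaks at 155/245/395/795 bp — the generator's
  four planted modes recovered to within one 10 bp histogram bin.
- `chrom_density.young.eccdna_vs_genes_per_mb`: R = 0.999 over the four
  chromosomes, reflecting the configured coupling of eccDNA rate to
  gene density (n = 4 chromosomes makes this a demonstration, not an
  inference).
- `genomic_annotation.normalized_coverage`: Gene2KbU 3.42, Gene2KbD
  3.34, CpG 0.67, intron 1.02 — the planted 3-fold gene-flank
  enrichment and CpG depletion stand out against the unenriched
  classes near 1.
- `junction_motif.young`: best trinucleotide `CCG`, best spacer 3 bp at
  offsets (−6, 0) with score 42.8 — the planted junction motif.
- `differential`: 337 significant of 2000 tested (237 up, 100 down)
  at |FC| ≥ 2 and q < 0.001, recovering the 300 planted fold changes
  (80% planted "up") plus a handful of overdispersion-driven calls.
- `conjoint.counts`: 59 eccDNAs and 39 genes shared with the synthetic
  differential-gene table in the same direction.

Every stage also writes its own TSV/JSON (`characterize.tsv`,
`chrom_density_<group>.tsv`, `normalized_coverage.tsv`,
`repeat_fraction.tsv`, `motif_profile.tsv`, `logo_matrix.tsv`,
`spacer_scan.json`, `differential.tsv`, `overlap_eccdnas.tsv`,
`venn.json`). Stage subcommands (`simulate`, `characterize`, `density`,
`annotate`, `motif`, `diff`, `conjoint`) expose the same computations
on individual inputs; see `examples/real_data_pipeline.yaml` for
running on your own called eccDNA data.

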