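# Template for running on called eccDNA data instead of a simulation:
# point the paths at your own files and remove the `simulate` section.
seed: 0
outdir: ecckit_out
group_order: [young, old]
paths:
  genome: /path/to/genome.fa            # reference FASTA (e.g. hg19)
  elements_dir: /path/to/elements       # <class>.bed per element class
  genes: /path/to/genes.bed             # chrom start end symbol
  de_genes: /path/to/de_genes.tsv       # symbol log2fc q direction
  counts: /path/to/counts.tsv           # eccDNA id x sample read counts
  samples: /path/to/samples.tsv         # sample<TAB>group
  eccdna_beds:
    Y1: /path/to/Y1.bed                 # Circle-Map style BED per sample
    O1: /path/to/O1.bed
params:
  exclude_chroms: []                    # e.g. [chrM]
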