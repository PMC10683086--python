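# Bundled synthetic demonstration: simulate a toy study, then run every
# analysis stage. `ecckit run --config examples/pipeline.yaml`
seed: 7
outdir: ecckit_out
simulate:
  seed: 7
  n_eccdna: 2000
  element_enrichment:
    Gene2KbU: 3.0
    Gene2KbD: 3.0
    CpG: 0.5
  planted_motif:
    trinucleotide: CCG
    spacer: 3
    fraction: 0.4
  de:
    n_differential: 300
    log2fc: 2.0
    up_fraction: 0.8
params:
  bin_width: 10
  flank_w: 10
  spacer_max: 8
  fc_threshold: 2.0
  q_threshold: 0.001
  pseudocount: 0.5
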