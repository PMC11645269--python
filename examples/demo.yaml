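# Demo run: simulate a four-protocol dissociation experiment in which 80% of
# the myeloid cells digested without inhibitors (ENZ-NONE) carry the
# activation program, then derive the consensus signature, calibrate the
# enrichment cutoff against random gene lists, and summarise per-sample
# enrichment. Runs in well under a minute.
seed: 7
out_dir: demo_run
stages:
  simulate:
    n_genes: 1000
    samples_per_group: 3
    cells_per_sample: 150
    activated_fraction:
      ENZ-NONE/myeloid: 0.8
  qc:
    min_genes_per_cell: 10
    min_umis: 50
    max_umis: 1.0e+9
    max_mito_fraction: 0.5
  normalize:
    scale: 10000.0
  pseudobulk:
    classes: [myeloid]
  de:
    comparisons:
      - [DNC-NONE, ENZ-NONE]
      - [DNC-INHIB, ENZ-NONE]
      - [ENZ-INHIB, ENZ-NONE]
  consensus: {}
  score:
    n_bins: 20
    ctrl_per_gene: 30
  calibrate:
    n_lists: 1000
    tail: 0.025
    n_bins: 20
    ctrl_per_gene: 30
  enrich:
    cell_class: myeloid
  correlate:
    covariates: [PMI, age]
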