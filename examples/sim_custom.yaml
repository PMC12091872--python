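# Fully explicit simulation spec (documents the schema).
seed: 42
sim:
  chrom_lengths: {chrA: 2000000, chrB: 1500000, chrC: 500000}
  f_het: 0.141          # genome fraction that is pericentromeric
  n_genes: 120
  tss_het_bias: 0.02    # probability a TSS falls in heterochromatin
  state_props:          # five chromatin colours + uncovered fraction
    BLACK: 0.20
    BLUE: 0.10
    GREEN: 0.10
    YELLOW: 0.25
    RED: 0.20
    UNASSIGNED: 0.15
  peak_sets:
    - label: ATAC-UP
      assay: ATAC
      n_peaks: 300
      theta_het: 0.30   # per-peak probability of heterochromatic placement
      direction_mix: {UP: 1.0}
      tier_mix: {0.05: 0.42, 0.01: 0.28, 0.001: 0.30}
    - label: ATAC-DOWN
      assay: ATAC
      n_peaks: 250
      theta_het: 0.141
      direction_mix: {DOWN: 1.0}
  tracks:
    - {label: HP1, coverage: 0.118, het_concentration: 0.35}
  expression:
    fraction_expressed: 0.55
    n_up: 20
    n_down: 15
    effect_size: 2.0
    noise_sd: 0.3
thresholds:
  alpha: 0.05
  min_bp: 1
  log2fc: 0.4
  significance: 0.05
  significance_kind: FDR
  tpm_cutoff: 1.0
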