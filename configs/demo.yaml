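# Demo run: a desk-scale end-to-end study (completes in well under a minute).
out_dir: runs/demo
seeds:
  truth: 101
  cohort: 102
  expression: 103
  spins: 104
  bootstrap: 105
  dge: 106
  cell_sets: 107
atlas:
  n_per_hemisphere: 40
  n_systems: 7
cohort:
  n_per_group: 40
  n_features: 7
  n_effect_regions: 8
  effect_size: 3.0
  noise_sd: 1.0
  smoothness: 0.4
expression_sim:
  n_genes: 400
  n_planted_genes: 40
  probes_per_gene: 3
  n_donors: 4
  samples_per_donor: 60
  n_bad_probes: 12
  n_background_probes: 30
msn:
  density: 1.0
tmap:
  covariates: [age, sex, education]
expression_prep:
  min_call_fraction: 0.5
  max_distance: 2.0
  ds_mode: top_fraction
  ds_threshold: 0.9
pls:
  n_spins: 199
  n_boot: 300
  z_threshold: 5.0
  fdr_threshold: 0.005
  standardize: true
genelists:
  dge:
    n_background: 250
    corr_strength: 0.7
    n_perm: 999
    direction: up
    alternative: two_sided
  cell_sets:
    sizes: [40, 30, 40, 35, 30, 15, 12]
    enrichment:
      astrocytes: 0.3
      excitatory_neurons: 0.25
      inhibitory_neurons: 0.2
    n_perm: 999
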