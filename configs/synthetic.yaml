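# Bundled synthetic-study pipeline configuration.
# The simulation block describes the emulated four-cohort design: two large
# training cohorts (45v65, 85v15) and two smaller validation cohorts
# (60v60, 25v25), 11x25-mer probe sets planted at graded identities, 40
# differential lncRNAs at |log2FC| = 1.5 on sigma = 0.7 noise, one
# up-regulated survival-marker lncRNA with hazard ratio 2, and gene sets
# with planted enrichment.
seed: 0
probe_identity: 0.90
set_fraction: 0.90
match_mode: probe_fraction
method: moderated
alpha: 0.01
k_top: 100
n_perm: 200
simulation:
  n_coding: 400
  n_lnc: 150
  n_probesets: 110
  n_decoy_probesets: 10
  probes_per_set: 11
  probe_length: 25
  identity_levels: [1.0, 0.96, 0.92, 0.88, 0.80]
  dataset_sizes: [[45, 65], [85, 15], [60, 60], [25, 25]]
  n_de: 40
  effect_log2fc: 1.5
  sigma: 0.7
  coexpr_module_size: 30
  coexpr_strength: 0.8
  n_survival: 200
  surv_true_loghr: 0.6931471805599453
  censor_rate: 0.2
  n_gene_sets: 20
  n_enriched_sets: 3
  set_size_range: [15, 50]
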