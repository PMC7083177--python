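# Demo run: five synthetic 10+10 case-control studies (one count-based),
# 5% of genes planted up and 5% down at delta = 1.5, one shifted outlier
# array per intensity study, a 400-node interactome with a 20-gene module
# planted on true DEGs, and 20 gene sets of which 5 are enriched.
seed: 1
outliers_first: true
cohort:
  n_studies: 5
  n_genes: 400
  n_case: 10
  n_control: 10
  frac_up: 0.05
  frac_down: 0.05
  effect_size: 1.5
  sigma: 0.5
  platform_mix: 0.2
  probe_multiplicity: 1.2
  frac_unannotated: 0.02
  n_outlier_arrays: 1
  dispersion: 0.1
network:
  n_nodes: 400
  attachment_m: 2
  module_size: 20
  module_extra_edge_prob: 0.6
  n_seeds: 5
gene_sets:
  n_sets: 20
  set_size: 40
  n_enriched_sets: 5
  enrichment_frac: 0.8
thresholds:
  deg_alpha: 0.05
  meta_alpha: 0.05
  edge_cutoff: 0.9
  hub_percentile: 95.0
  n_iter: 15
  min_reports: 2
  seed_p_cutoff: 1.0e-8
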