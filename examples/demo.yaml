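# Small end-to-end demo configuration (runs in about a minute).
seed: 5
simulation:
  n_founders: 60
  n_generations: 3
  n_snps: 300
  n_otus: 25
  depth_range: [1500, 3000]
  fixed_effect_levels:
    year: 3
    lactation: 2
    litter_size: 2
    run: 3
    time_order: 3
    total_seq_class: 3
    test_day: 3
em_rounds: 10
reml_tol: 1.0e-6
reml_max_iter: 30
n_perm: 40
rg_traits: [fat_content, milk_yield]
rg_max_pairs: 2
gwas_targets: [fat_content]
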