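# Demo study configuration: a two-region synthetic cohort emulating the
# contrast between a small, poorly-consistent structure (amygdala) and a
# larger, well-consistent one (hippocampus), plus desk-scale Monte-Carlo
# settings for the discordance grid and the resampling study.
#
# Amygdala method_asymmetry values are sized so that, on the pooled-SD
# standardized scale (analytic pooled SD ≈ 457 mm³ for this model), the
# planted left-right contrasts are ≈ +0.04 for method 1 and ≈ -0.19 for
# method 2, i.e. an interaction of ≈ 0.23.

seed: 7

cohort:
  n_participants: 20000
  seed: 7
  methods: [fsl, freesurfer]
  regions:
    - name: amygdala
      mean_volume: 1500        # mm³ latent mean
      between_subject_sd: 200
      target_consistency: 0.2
      method_offset: 150       # method-2 additive bias
      hemisphere_asymmetry: 0
      method_asymmetry: [18, -87]
      hemisphere_correlation: 0.8
    - name: hippocampus
      mean_volume: 3800
      between_subject_sd: 350
      target_consistency: 0.65
      method_offset: -250
      hemisphere_asymmetry: 80
      method_asymmetry: [10, 10]
      hemisphere_correlation: 0.8
  confounds:
    - name: head_size
      kind: continuous
      loading_per_method: [40, 40]   # shared confound: inflates apparent consistency
    - name: site
      kind: categorical
      n_levels: 3
      loading_per_method: [15, 10]
    - name: age
      kind: continuous
      loading_per_method: [8, 8]
    - name: scanner_position
      kind: continuous
      loading_per_method: [5, 0]     # method-specific sensitivity
  phenotypes:
    - {name: fluid_intelligence, region: amygdala, true_correlation: 0.15, missing_rate: 0.10}
    - {name: reaction_time, region: amygdala, true_correlation: 0.12, missing_rate: 0.05}
    - {name: numeric_memory, region: amygdala, true_correlation: 0.10, missing_rate: 0.20}
    - {name: pairs_matching, region: amygdala, true_correlation: 0.08, missing_rate: 0.05}
    - {name: prospective_memory, region: amygdala, true_correlation: 0.06, missing_rate: 0.15}
    - {name: trail_making, region: amygdala, true_correlation: 0.05, missing_rate: 0.25}
    - {name: symbol_digit, region: amygdala, true_correlation: 0.04, missing_rate: 0.10}
    - {name: matrix_completion, region: amygdala, true_correlation: 0.02, missing_rate: 0.05}
    - {name: tower_rearranging, region: amygdala, true_correlation: 0.01, missing_rate: 0.15}
    - {name: picture_vocabulary, region: amygdala, true_correlation: 0.0, missing_rate: 0.05}

simulate:
  iccs: [0.2, 0.4, 0.6, 0.8, 0.95]
  rhos: [0.01, 0.1, 0.2]
  ns: [50, 100]
  n_experiments: 200   # demo scale; batch engine defaults are 500 × 200
  n_batches: 100
  alpha: 0.05
  seed: 7

resample:
  region: amygdala
  hemisphere: left
  top_k: 10
  ns: [50, 100]
  n_experiments: 100   # demo scale
  n_batches: 20
  alpha: 0.05
  seed: 7
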