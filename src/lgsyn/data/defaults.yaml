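# Default configuration constants.
#
# cutoffs: recommended diagnostic thresholds for classify(), per scheme
# (the published maximum-efficiency cutoffs of the two instrument variants:
# 75.00% for the category scheme, 26.06% for the five-taste scheme).
# Overridable everywhere they are used.
cutoffs:
  category: 75.00
  five_taste: 26.06

# Simulator calibration.  Responder parameters for synthetic synesthete and
# control cohorts, per scheme.  Calibrated by Monte-Carlo so that default
# cohorts reproduce the instrument's published group medians (category:
# ~85.9 vs ~45.0; five-taste: ~67.8 vs ~13.3).
simulator:
  default_n_syn: 28
  default_n_control: 57
  default_n_words: 30
  rng_algorithm: PCG64
  category:
    synesthete:
      p_taste: 0.95
      p_exact: 0.92
      p_partial: 0.04
      intensity_mu: 57.0
      intensity_sd: 18.0
      intensity_noise_sd: 10.0
    control:
      p_taste: 0.95
      p_exact: 0.40
      p_partial: 0.13
      intensity_mu: 40.0
      intensity_sd: 18.0
      intensity_noise_sd: 25.0
  five_taste:
    synesthete:
      p_taste: 0.93
      concentration: 30.0
      profile_sparsity: 0.5
    control:
      p_taste: 0.93
      concentration: 0.62
      profile_sparsity: 0.5
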