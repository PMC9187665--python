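# Small end-to-end fixture: 20 mRNAs, 60 mRNA-channel frames (590 s at
# 10 s spacing), 5 Z planes.  The mean + k*SD threshold is used because the
# fields are sparse (Otsu needs a bimodal histogram).
simulation:
  field_size_px: [128, 128]
  n_z_planes: 5
  duration_s: 590.0
  n_mrna: 20
  diffusion_coeff_um2_s: 0.02
  rng_seed: 2024
kinetics:
  init_rate_per_s: 0.0333333333
  elongation_rate_aa_s: 2.0
  tether_on_rate_per_s: 0.005
  tether_off_rate_per_s: 0.01
detection:
  threshold_policy: mean_plus_k_sd
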