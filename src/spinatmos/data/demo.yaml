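# spinatmos demonstration pipeline: OU validation, static-sampler oracle,
# planted-accumulation recovery, electrolyte setup, relaxometry forecast.
seed: 7
outdir: spinatmos_out
stages:
  - ou_validation:
      n_steps: 200000
      tau_c: 0.1
      dt: 0.01
  - static_noise:
      n_frames: 30
  - planted_recovery:
      levels: [2, 8]
      n_seeds: 3
      n_frames: 100
  - electrolyte_setup: {}
  - relaxometry_forecast: {}
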