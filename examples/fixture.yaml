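# Small synthetic-world fixture exercising every pipeline stage.
out_dir: fixture_out
seed: 11
stages: [simulate, clean, niche, divrate, spatial, profile]
simulate:
  min_tips: 25
  max_tips: 150
  n_per_species: 8
  climate_cell_deg: 2.0
divrate:
  starts: 1
  models: [lambda_const, lambda_linT, lambda_expT]
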