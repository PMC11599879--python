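# Demo pipeline configuration for `mcpi run --config examples/demo_config.yaml`
seed: 42
out_dir: scratch/cli_demo

scene:
  n_cols: 240
  n_rows: 80
  pixel_size: 30.0
  width_m: [600, 1100, 1500, 450, 900, 1300]
  height_m: [3.0, 6.0, 9.0, 2.0, 11.0, 7.0]
  ndvi: [0.55, 0.65, 0.75, 0.5, 0.8, 0.7]
  n_regions: 6

epochs:
  - {year: 2007}
  - {year: 2013, width_factor: 0.97, height_factor: 0.90}
  - {year: 2019, width_factor: 0.95, height_factor: 0.80, ndvi_factor: 1.02}

sampling:
  spacing: 500.0
  length: 6000.0

index:
  rate: 0.29
  exponent: 2.55
  cap_m: 10.0
  scale: 1000.0

cena:
  k: 3
  bootstrap: 50

validation:
  n_storms: 8
  wind_range: [50.0, 130.0]
  wind_threshold_kn: 64.0
  buffer_m: 500.0
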