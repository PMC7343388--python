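# Demo configuration for the end-to-end pipeline:
#   sgnpos run examples/pipeline_config.yaml --output-dir demo_run
# Simulates a small population, extracts features, fits the position models
# and writes the report tables; completes in well under a minute.
seed: 7
simulation:
  n_neurons: 40
  age_range: [3, 10]
model:
  subsets: [spiking_only, pooled]
  age_range: [3, 10]
output_dir: demo_run
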