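# A small original-image vs translated comparison driven by the CLI:
#   myoseg experiment --config examples/experiment.yaml
# Writes results.csv (method,config,subject_id,dsc) and summary.csv
# (median/quartiles/min/max per method x configuration) plus a
# reproducibility record to output_dir.
seed: 1
output_dir: runs/experiment_demo
n_easy_subjects: 6
n_hard_subjects: 6
slices_per_subject: 3
image_size: 64
preset: tiny
train_overrides:
  epochs: 8
methods: [gmm]
configs:
  - OI
  - {wr: 0.5, wi: 1.0}
annotation_step: 1
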