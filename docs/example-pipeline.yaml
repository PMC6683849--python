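# Example multi-stage run: synthetic frames -> train -> evaluate -> dream.
# Execute with: spectnet run --config docs/example-pipeline.yaml
stages: [simulate, train, evaluate, dream]
seed: 0
output_dir: spectnet-run
run_id: demo

simulate:
  mode: frames            # or "eeg" for raw-signal simulation
  n_subjects_per_class: 10
  frames_per_subject: 148
  # recipes:              # omit to use the default 10 Hz vs 6 Hz task
  #   - label: A
  #     burst_specs: [{center_frequency: 10.0}]
  #   - label: B
  #     burst_specs: [{center_frequency: 6.0, burst_width_time: 2.0}]

train:
  arch: dcnn              # dcnn | rnn | shallow
  params: {n_steps: 1000}

evaluate:
  arch: dcnn
  params: {n_steps: 1000}
  n_experiments: 10

dream:
  n_steps: 200
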