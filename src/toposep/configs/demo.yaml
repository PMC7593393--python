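# Demo workflow: synthetic SEP study, small enough to run in seconds.
# Five subjects x three stimulation frequencies at one location, reduced
# 20-channel montage, 125 Hz sampling.
seed: 7
input:
  simulate:
    n_subjects_per_group: 5
    freq_labels: ["0.5Hz", "1.1Hz", "1.6Hz"]
    locations: ["BD"]
    n_trials: 12
    noise_sd_uv: 1.0
    sampling_rate: 125
    n_channels: 20
markers:
  enable: true
  channel_pair: "Cz-AvgRef"
windows:
  enable: true
topostats:
  enable: true
  n_perm: 199
microstates:
  enable: true
  k_grid: [3, 6]
  n_repeats: 8
  n_perm: 199
plots:
  enable: false
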