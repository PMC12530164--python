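# Demo pipeline configuration: a small cohort that runs end to end in minutes.
# ambddm all -c examples/config.yaml --seed 1 -o runs/demo
out_dir: runs/demo
seed: 1
cohort:
  n_participants: 16
  conditions:
    - {study_time: short_500ms, change_prob: low_50, urgency: minimal_10000ms, probe_type: single_probe}
    - {study_time: short_500ms, change_prob: high_80, urgency: minimal_10000ms, probe_type: single_probe}
    - {study_time: short_500ms, change_prob: low_50, urgency: high_3000ms, probe_type: single_probe}
    - {study_time: short_500ms, change_prob: high_80, urgency: high_3000ms, probe_type: single_probe}
  session_missing_prob: 0.0845
  contaminant_rate: 0.0009
  seed: 0
model:
  chains: 2
  warmup: 400
  draws: 400
  seed: 0
ppc_n_sim: 200
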