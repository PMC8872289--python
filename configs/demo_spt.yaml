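# Demo SPT pipeline config: pure simulation of a two-state mixture in a rod
# cell, analyzed end to end (filter -> MSD -> SQD mixture -> dwell -> map).
# Run:  divtrack spt --config configs/demo_spt.yaml --out results/demo
components:
  - [0.005, 0.6]   # [D in um^2/s, population fraction]
  - [0.3, 0.4]
frame_interval: 0.024   # seconds (20 ms exposure + transfer)
n_tracks: 400
n_components: 2
loc_error_sd: 0.02      # um
bleach_prob_per_frame: 0.05
condition: demo
seed: 7
geometry:
  shape: rod
  length: 3.0   # um, cap to cap
  width: 1.0    # um
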