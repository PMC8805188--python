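# Desk-scale study configuration for `rhi-mvpa run` / `rhi-mvpa simulate`.
# Full-design values would be: n_participants: 22, n_channels: 128,
# trials_per_condition: 4, events_per_trial: 180, decoding.n_repeats: 50,
# cluster.n_randomizations: 5000, onset medians 42 / 30 s.
study:
  n_participants: 12
  n_channels: 32
  trials_per_condition: 2
  events_per_trial: 60

effects:
  - id: illusion_state
    contrast: [Illusion, Incongruent]   # family labels expand to both hand positions
    window: [0.08, 0.30]                # seconds post-stimulus
    amplitude: 5.0                      # uV along a unit-norm channel pattern
    pattern_mode: participant-specific

decoding:
  n_repeats: 10
  bin_step: 0.02

cluster:
  n_randomizations: 2000

onset_median_next: 21.0    # seconds (scaled to the 60-s trials)
onset_median_under: 15.0
onset_sigma: 0.3

scr_effect:
  IllusionNext: 1.5
  IllusionUnder: 1.5
scr_effect_window: [-3.0, 0.0]   # pre-onset arousal rise

master_seed: 1
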