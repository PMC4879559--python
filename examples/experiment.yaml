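# Three-arm synthetic experiment: vehicle control, full activity blockade
# (calcium transients silenced, intrinsic turnover intact), and an enriched
# arm with doubled spine generation.
seed: 1
n_dendrites_per_condition: 10
n_populations_per_condition: 3
matching_tolerance_um: 1.0
detection:
  sd_multiplier: 3.0
  min_run_frames: 3
  active_spine_min_exceedances: 4
stats:
  control: control
  alpha: 0.05
  n_mc: 10000
conditions:
  - label: control
    sim:
      n_spines_per_dendrite: 100
      n_sessions: 6
  - label: blockade
    sim:
      n_spines_per_dendrite: 100
      n_sessions: 6
      shaft_event_rate_hz: 0.0
      spine_specific_rate_hz: 0.0
  - label: enriched
    sim:
      n_spines_per_dendrite: 100
      n_sessions: 6
      p_gen: 0.10
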