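# Phase I - shaping: simple stimulus-response association.
# A fixed 3 s ITI precedes a 10 s full-contrast drifting grating; any
# screen contact during the stimulus earns a 10 ul water reward followed
# by a 1 s consumption delay. Misses and uncued touches are not punished.
protocol: single_target
session_duration_s: 1800.0     # 30 min daily session
iti_range_s: [3.0, 3.0]        # fixed-length ITI
stimulus_duration_s: 10.0
reward_delay_s: 1.0
dead_zone_mm: 0.0
corrections_enabled: false
reward_volume_ul: 10.0
response_modality: nose_poke
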