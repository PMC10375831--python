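# Phase II - 2AFC nose poke: drifting-grating target vs isoluminant-gray
# distractor on pseudo-randomly ordered sides, separated by a 10 mm
# central dead zone where touches are not registered. The ITI is drawn
# uniformly from 4-6 s. An incorrect choice triggers a correction trial
# (same placement until correct).
protocol: twoafc
session_duration_s: 1800.0
iti_range_s: [4.0, 6.0]        # pseudo-randomized ITI
stimulus_duration_s: 10.0
reward_delay_s: 1.0
dead_zone_mm: 10.0
corrections_enabled: true
reward_volume_ul: 10.0
response_modality: nose_poke
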