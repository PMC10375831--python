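# Phase III - 2AFC reaching: identical task structure to Phase II, but
# the arena insert forces forelimb reaches instead of nose pokes. The
# tag routes reach-scatter analytics (pairwise paw-placement distance).
protocol: twoafc
session_duration_s: 1800.0
iti_range_s: [4.0, 6.0]
stimulus_duration_s: 10.0
reward_delay_s: 1.0
dead_zone_mm: 10.0
corrections_enabled: true
reward_volume_ul: 10.0
response_modality: reaching
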