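session_minutes: 75.0
dwell_in_min: 8.0
dwell_out_min: 10.0
shared_gain: 0.25
signal_scale: 1.0
identical_profiles: false
dup_rate: 0.02
gap_rate: 0.02
latency_mean_s: 5.0
latency_sd_s: 2.0
miss_prob: 0.0
verbose_reemit_min: 2.5
time_scale: 1.0
balance_band:
- 0.35
- 0.65
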