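session_minutes: 10.0
dwell_in_min: 1.0666666666666667
dwell_out_min: 1.3333333333333333
shared_gain: 0.25
signal_scale: 1.0
identical_profiles: false
dup_rate: 0.02
gap_rate: 0.02
latency_mean_s: 0.6666666666666666
latency_sd_s: 0.26666666666666666
miss_prob: 0.0
verbose_reemit_min: 0.3333333333333333
time_scale: 0.13333333333333333
balance_band:
- 0.35
- 0.65
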