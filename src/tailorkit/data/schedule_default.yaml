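# Program calendar in day offsets from baseline.
wave_count: 3
inter_wave_gap_days: 42
update_card_offsets: [28, 56]
fallback_window_days: 14
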