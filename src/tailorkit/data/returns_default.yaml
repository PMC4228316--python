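# Joint update-card return pattern.  The published marginals (card 1: 70%,
# card 2: 60%, both: 49%) fix three cells; "neither" (0.19) absorbs the
# remainder.  Delays are in-window because the published rates count
# returns within the two-week window.
p_both: 0.49
p_only_card1: 0.21
p_only_card2: 0.11
p_neither: 0.19
delay_mean: 8.0
delay_sd: 3.0
delay_min: 1.0
delay_max: 14.0
activity_p_meet: 0.235
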