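# Breathing-frequency simulation grid: normal data, three dispersion
# levels, flat / linear / exponential trends, no sighs.
name: table_bf
parameter: bf
rest_mean: 18.0
end_mean: 39.0
n_cycles: 300
sd_levels: [2.0, 4.0, 6.0]
trends: [flat, linear, exponential]
sighs: false
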