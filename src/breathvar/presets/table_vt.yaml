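# Tidal-volume simulation grid: normal data, three dispersion levels,
# flat / linear / logarithmic trends, no sighs.
name: table_vt
parameter: vt
rest_mean: 790.0
end_mean: 2130.0
n_cycles: 300
sd_levels: [60.0, 270.0, 500.0]
trends: [flat, linear, logarithmic]
sighs: false
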