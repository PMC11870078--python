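# Tidal-volume simulation grid with sigh contamination: sighs drawn from
# Normal(3500, 200) mL replace cycles about every 15 cycles (SD 3, never
# closer than 4 apart); overall SD re-adjusted to the nominal level.
name: table_vt_sighs
parameter: vt
rest_mean: 790.0
end_mean: 2130.0
n_cycles: 300
sd_levels: [60.0, 270.0, 500.0]
trends: [flat, linear, logarithmic]
sighs: true
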