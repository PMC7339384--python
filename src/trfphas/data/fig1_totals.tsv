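library	class	rpm_total
C1D	miRNA	833750
C1D	tRF	50520
C1D	phasiRNA	115728
A1D	miRNA	843038
A1D	tRF	42954
A1D	phasiRNA	114008
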