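item	c1d_rpm	a1d_rpm
trf_ENSRNA049443699:1-20	30155.81	24539.08
trf_down_total	33315.52	26572.77
trf_up_total	663.41	840.83
phasirna_down_total	10715.98	6710.06
phasirna_up_total	3715.64	5529.62
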