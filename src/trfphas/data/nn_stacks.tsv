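stack	dg
AA/UU	-0.93
AU/UA	-1.10
UA/AU	-1.33
CU/GA	-2.08
CA/GU	-2.11
GU/CA	-2.24
GA/CU	-2.35
CG/GC	-2.36
GG/CC	-3.26
GC/CG	-3.42
AG/UU	-0.55
AU/UG	-1.36
UA/GU	-1.27
GA/UU	-1.29
CG/GU	-2.11
CU/GG	-1.53
GG/CU	-1.77
GC/UG	-2.17
GG/UU	-0.50
GU/UG	-0.23
UG/GU	-0.56
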