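motif	dpsi	source_id
GG	-0.74	toyC1
RG	-0.62	toyC2
KG	-0.58	toyC3
EE	-0.47	toyC4
PG	-0.44	toyC5
VV	-0.41	toyC6
SS	-0.25	toyC7
AA	-0.10	toyC8
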