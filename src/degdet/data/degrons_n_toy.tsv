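motif	dpsi	source_id
RV	-0.66	toyN1
DI	-0.58	toyN2
GK	-0.52	toyN3
LL	-0.47	toyN4
EE	-0.42	toyN5
TT	-0.33	toyN6
NQ	-0.15	toyN7
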