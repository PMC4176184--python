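step	trx
AA	5.0
AC	4.0
AG	9.0
AT	0.0
CA	42.0
CC	42.0
CG	43.0
GA	22.0
GC	25.0
TA	14.0
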