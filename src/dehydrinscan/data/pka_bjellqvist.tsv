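# Bjellqvist pKa set (ExPASy ProtParam convention); sign: +1 basic, -1 acidic
# site	pka	charge_sign
NTERM	7.5	1
CTERM	3.55	-1
K	10.0	1
R	12.0	1
H	5.98	1
D	4.05	-1
E	4.45	-1
C	9.0	-1
Y	10.0	-1
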