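# RC conformation probabilities, beta-D-galactopyranose (MD-free ED analysis)
# columns: label	rotamer	probability
A	GT	0.09
B	GT	0.16
C	GT	0.13
D	GT	0.12
E	GG	0.19
F	GG	0.18
G	GG	0.07
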