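# RC conformation probabilities, alpha-D-galactopyranose (MD-free ED analysis)
# columns: label	rotamer	probability
A	GT	0.15
B	GT	0.15
C	GT	0.12
D	GT	0.15
E	GG	0.19
F	GG	0.19
G	GG	0.05
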